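"""The five random item generation (RIG) tasks.

Each task asks a participant to produce a short pseudo-random arrangement
of a fixed set of alternatives:

==========  ======================================  ========  ======
task_id     response                                alphabet  length
==========  ======================================  ========  ======
coin        12 coin tosses (heads/tails)                   2      12
card        10 guesses among 5 Zener cards                 5      10
die         10 die rolls (faces 1-6)                       6      10
circles     10 pointings at one of 9 circles               9      10
grid        a 3x3 binary grid (final configuration)        2     3x3
==========  ======================================  ========  ======

Responses are stored as 0-based digit strings (the grid row-major).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TaskSpec", "TASKS", "TASK_ORDER"]


@dataclass(frozen=True)
class TaskSpec:
    """Alphabet, shape and scoring configuration of one RIG task."""

    task_id: str
    alphabet_size: int
    length: int
    dimension: int
    table_ref: str
    #: BDM block shape: an int for sequences, (rows, cols) for the grid.
    block_shape: int | tuple[int, int]
    shape: tuple[int, int] | None = None  # grid geometry, dimension 2 only

    @property
    def n_strings(self) -> int:
        """Size of the full response space, alphabet_size ** length."""
        return self.alphabet_size**self.length


#: Block length 3 is the longest block fully covered by the shipped binary
#: table (every canonical binary class of length <= 3 appears in the
#: exhaustive (2,2) output distribution); the sampled multi-symbol tables
#: cover all five canonical classes of length 3 as well.
TASKS: dict[str, TaskSpec] = {
    "coin": TaskSpec("coin", 2, 12, 1, "bin1d", 3),
    "card": TaskSpec("card", 5, 10, 1, "sym5", 3),
    "die": TaskSpec("die", 6, 10, 1, "sym6", 3),
    "circles": TaskSpec("circles", 9, 10, 1, "sym9", 3),
    "grid": TaskSpec("grid", 2, 9, 2, "bin2d", (1, 3), shape=(3, 3)),
}

#: Fixed presentation order of the tasks.
TASK_ORDER = ["coin", "card", "die", "circles", "grid"]
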