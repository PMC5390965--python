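"""Built-in desk-scale CTM tables.

The published complexity tables behind the acss ecosystem rest on spaces of
up to ~2.7e13 machines; at desk scale this package rebuilds much smaller
spaces deterministically in seconds and accepts that absolute K values
differ from the published ones (orderings of simple vs complex strings are
what the analysis needs).

========  =========================================================
name      machine space
========  =========================================================
bin1d     (2 states, 2 symbols, 1-D), exhaustive, step cap 6
bin2d     (2 states, 2 symbols, 2-D turmites), exhaustive, cap 500
sym5      (2, 5, 1-D), 200 000 sampled machines, cap 500
sym6      (2, 6, 1-D), 200 000 sampled machines, cap 500
sym9      (2, 9, 1-D), 200 000 sampled machines, cap 500
========  =========================================================

Sampled builds use a fixed internal seed so every process reconstructs
bit-identical tables.
"""

from __future__ import annotations

from functools import lru_cache

from .ctm import CTMTable, coding_theorem
from .machines import MachineSpace, enumerate_space, sample_space
from .tasks import TASKS

__all__ = ["builtin_table", "table_for_task", "BUILTIN_SPACES", "TABLE_SEED"]

#: Internal seed for the sampled builtin spaces (fixed so tables are stable).
TABLE_SEED = 20170413

SAMPLE_SIZE = 200_000

BUILTIN_SPACES: dict[str, MachineSpace] = {
    "bin1d": MachineSpace(2, 2, dimension=1),
    "bin2d": MachineSpace(2, 2, dimension=2),
    "sym5": MachineSpace(2, 5, mode="sampled", sample_size=SAMPLE_SIZE, seed=TABLE_SEED),
    "sym6": MachineSpace(2, 6, mode="sampled", sample_size=SAMPLE_SIZE, seed=TABLE_SEED),
    "sym9": MachineSpace(2, 9, mode="sampled", sample_size=SAMPLE_SIZE, seed=TABLE_SEED),
}


@lru_cache(maxsize=None)
def builtin_table(name: str) -> CTMTable:
    """Build (once per process) and return a named builtin CTM table."""
    try:
        space = BUILTIN_SPACES[name]
    except KeyError:
        raise KeyError(
            f"unknown builtin table {name!r}; available: {sorted(BUILTIN_SPACES)}"
        ) from None
    if space.mode == "exhaustive":
        dist = enumerate_space(space)
    else:
        dist = sample_space(space)
    return coding_theorem(dist)


def table_for_task(task_id: str) -> CTMTable:
    return builtin_table(TASKS[task_id].table_ref)
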