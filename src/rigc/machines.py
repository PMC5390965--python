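"""Enumeration and simulation of small Turing machines.

The machine formalism is the classic (n states, k symbols) Turing machine
with a distinguished halt target: for every (state, read symbol) pair the
transition table either specifies (write symbol, move, next state) or
(write symbol, halt).  In one dimension the head moves left/right, so each
table cell has ``2*k*n + k`` possible entries; in two dimensions (turmites
on an infinite grid) the move set is up/down/left/right and the cell has
``4*k*n + k`` entries.  A machine is identified with its transition table,
i.e. with an integer in ``range(n_entries ** (k*n))``.

Every run starts on an all-blank tape (blank symbol 0) with the head at the
origin in state 0.  A run that has not executed a halting transition within
``step_cap`` steps is discarded (excluded from numerator and denominator of
the output-frequency distribution).  The output of a halting run is the
tape segment spanned by every cell the head visited, read left-to-right
(for 2-D, the minimal bounding rectangle of visited cells, read row by
row); a machine halting on its first step outputs the single origin cell.

Outputs are recorded in canonical symbol order (first distinct symbol
becomes 0, the next 1, ...), which removes the arbitrary identity of the
non-blank symbols and guarantees permutation invariance downstream.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "MachineSpace",
    "FrequencyDistribution",
    "BUSY_BEAVER_STEPS",
    "enumerate_space",
    "enumerate_space_naive",
    "sample_space",
    "canonical_relabel",
]

#: Known maximal step counts of halting machines ("busy beaver" bounds) for
#: 1-D spaces, used as default (and minimal safe) simulation cutoffs.
BUSY_BEAVER_STEPS: dict[tuple[int, int], int] = {(2, 2): 6, (3, 2): 21, (4, 2): 107}

DEFAULT_STEP_CAP = 500

#: Refuse exhaustive enumeration beyond this many machines.
ENUMERATION_BUDGET = 10**8


@dataclass(frozen=True)
class MachineSpace:
    """A finite space of small Turing machines.

    Parameters
    ----------
    n_states, n_symbols
        Size of the machine's state set and tape alphabet (symbol 0 is the
        blank).
    dimension
        1 for tape machines, 2 for turmites.
    step_cap
        Maximum number of steps (the halting transition counts as a step)
        before a run is declared non-halting.  Defaults to the known busy
        beaver bound where one is known, 500 otherwise.
    mode
        ``"exhaustive"`` or ``"sampled"``.
    sample_size, seed
        Required in sampled mode: number of machines drawn uniformly (with
        replacement) from the space, and the RNG seed.
    """

    n_states: int
    n_symbols: int
    dimension: int = 1
    step_cap: int | None = None
    mode: str = "exhaustive"
    sample_size: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_states < 1 or self.n_symbols < 1:
            raise ValueError("n_states and n_symbols must be positive")
        if self.dimension not in (1, 2):
            raise ValueError("dimension must be 1 or 2")
        if self.step_cap is None:
            cap = BUSY_BEAVER_STEPS.get((self.n_states, self.n_symbols))
            if cap is None or self.dimension == 2:
                cap = DEFAULT_STEP_CAP
            object.__setattr__(self, "step_cap", cap)
        if self.step_cap < 1:
            raise ValueError("step_cap must be >= 1")
        if self.mode not in ("exhaustive", "sampled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "sampled":
            if self.sample_size is None or self.sample_size < 1:
                raise ValueError("sampled mode requires sample_size >= 1")
            if self.seed is None:
                raise ValueError("sampled mode requires an explicit seed")

    @property
    def n_moves(self) -> int:
        return 2 * self.dimension

    @property
    def n_cells(self) -> int:
        """Transition-table cells: one per (state, read symbol) pair."""
        return self.n_states * self.n_symbols

    @property
    def n_entry_options(self) -> int:
        """Possible entries per cell: (write, move, state) triples + halting writes."""
        return self.n_moves * self.n_symbols * self.n_states + self.n_symbols

    @property
    def n_machines(self) -> int:
        return self.n_entry_options**self.n_cells

    def describe(self) -> dict:
        return {
            "n_states": self.n_states,
            "n_symbols": self.n_symbols,
            "dimension": self.dimension,
            "step_cap": self.step_cap,
            "mode": self.mode,
            "sample_size": self.sample_size,
            "seed": self.seed,
        }


@dataclass
class FrequencyDistribution:
    """Output-frequency distribution over a machine space.

    ``counts`` maps each canonical output (1-D: a digit string; 2-D: digit
    rows joined by "/") to the number of halting machines that produced it;
    ``total_halting`` is the number of halting runs, i.e. ``sum(counts)``.
    """

    space: MachineSpace
    counts: dict[str, int] = field(default_factory=dict)
    total_halting: int = 0

    def frequency(self, key: str) -> float:
        return self.counts.get(key, 0) / self.total_halting


def canonical_relabel(symbols) -> tuple[int, ...]:
    """Relabel integer symbols by order of first occurrence (idempotent)."""
    mapping: dict[int, int] = {}
    out = []
    for s in symbols:
        if s not in mapping:
            mapping[s] = len(mapping)
        out.append(mapping[s])
    return tuple(out)


def _canonical_key_1d(cells) -> str:
    return "".join(str(c) for c in canonical_relabel(cells))


def _canonical_key_2d(rect: np.ndarray) -> str:
    flat = canonical_relabel(int(v) for v in rect.ravel())
    ncol = rect.shape[1]
    rows = ["".join(str(v) for v in flat[i : i + ncol]) for i in range(0, len(flat), ncol)]
    return "/".join(rows)


# ---------------------------------------------------------------------------
# Naive reference simulator (1-D): the tape is a growing list of written
# cells addressed by a dict.  Deliberately kept independent of the numba
# kernels so it can serve as an oracle for them.
# ---------------------------------------------------------------------------


def _decode_entry_1d(entry: int, n_states: int, n_symbols: int):
    """-> (write, move, next_state) with next_state=-1 meaning halt; move in {-1,+1}."""
    if entry < 2 * n_symbols * n_states:
        write = entry % n_symbols
        rest = entry // n_symbols
        move = -1 if rest % 2 == 0 else 1
        return write, move, rest // 2
    return entry - 2 * n_symbols * n_states, 0, -1


def simulate_naive(entries, space: MachineSpace) -> str | None:
    """Run one 1-D machine given its transition entries; canonical output or None."""
    tape: dict[int, int] = {}
    pos, state = 0, 0
    lo = hi = 0
    for _ in range(space.step_cap):
        read = tape.get(pos, 0)
        write, move, nxt = _decode_entry_1d(
            entries[state * space.n_symbols + read], space.n_states, space.n_symbols
        )
        tape[pos] = write
        if nxt < 0:
            return _canonical_key_1d(tape.get(p, 0) for p in range(lo, hi + 1))
        pos += move
        lo, hi = min(lo, pos), max(hi, pos)
        state = nxt
    return None


def enumerate_space_naive(space: MachineSpace) -> FrequencyDistribution:
    """Exhaustive enumeration with the naive simulator (1-D only; oracle path)."""
    if space.dimension != 1:
        raise ValueError("naive enumeration implemented for dimension 1 only")
    _check_exhaustive(space)
    base, cells = space.n_entry_options, space.n_cells
    counts: Counter[str] = Counter()
    for m in range(space.n_machines):
        entries = []
        x = m
        for _ in range(cells):
            entries.append(x % base)
            x //= base
        key = simulate_naive(entries, space)
        if key is not None:
            counts[key] += 1
    return FrequencyDistribution(space, dict(counts), sum(counts.values()))


# ---------------------------------------------------------------------------
# Optimized kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _run_chunk_1d(entry_tables, n_states, n_symbols, step_cap, out_buf, out_len):
    """Simulate a batch of 1-D machines; write raw outputs into out_buf."""
    n_mach = entry_tables.shape[0]
    width = 2 * step_cap + 3
    origin = step_cap + 1
    tape = np.zeros(width, dtype=np.uint8)
    for i in range(n_mach):
        pos = origin
        lo = origin
        hi = origin
        state = 0
        halted = False
        for _ in range(step_cap):
            read = tape[pos]
            entry = entry_tables[i, state * n_symbols + read]
            if entry < 2 * n_symbols * n_states:
                tape[pos] = entry % n_symbols
                rest = entry // n_symbols
                if rest % 2 == 0:
                    pos -= 1
                    if pos < lo:
                        lo = pos
                else:
                    pos += 1
                    if pos > hi:
                        hi = pos
                state = rest // 2
            else:
                tape[pos] = entry - 2 * n_symbols * n_states
                halted = True
                break
        if halted:
            n = hi - lo + 1
            out_len[i] = n
            for j in range(n):
                out_buf[i, j] = tape[lo + j]
        else:
            out_len[i] = -1
        for p in range(lo, hi + 1):  # restore blank tape for the next machine
            tape[p] = 0
    return out_buf


@njit(cache=True)
def _run_chunk_2d(entry_tables, n_states, n_symbols, step_cap, buf, offsets, out_dims, start):
    """Simulate a batch of turmites; bounding rectangles go into a flat buffer.

    Outputs are written row-major at ``offsets[i]``; returns ``(i_stop,
    cursor)`` where ``i_stop < n_mach`` signals a full buffer (caller
    flushes and resumes from there).
    """
    n_mach = entry_tables.shape[0]
    width = 2 * step_cap + 3
    origin = step_cap + 1
    cursor = 0
    tape = np.zeros((width, width), dtype=np.uint8)
    for i in range(start, n_mach):
        r = origin
        c = origin
        rlo = rhi = origin
        clo = chi = origin
        state = 0
        halted = False
        for _ in range(step_cap):
            read = tape[r, c]
            entry = entry_tables[i, state * n_symbols + read]
            if entry < 4 * n_symbols * n_states:
                tape[r, c] = entry % n_symbols
                rest = entry // n_symbols
                move = rest % 4
                if move == 0:
                    r -= 1
                elif move == 1:
                    r += 1
                elif move == 2:
                    c -= 1
                else:
                    c += 1
                if r < rlo:
                    rlo = r
                elif r > rhi:
                    rhi = r
                if c < clo:
                    clo = c
                elif c > chi:
                    chi = c
                state = rest // 4
            else:
                tape[r, c] = entry - 4 * n_symbols * n_states
                halted = True
                break
        if halted:
            nr = rhi - rlo + 1
            nc = chi - clo + 1
            if cursor + nr * nc > buf.size:
                for rr in range(rlo, rhi + 1):
                    for cc in range(clo, chi + 1):
                        tape[rr, cc] = 0
                return i, cursor
            out_dims[i, 0] = nr
            out_dims[i, 1] = nc
            offsets[i] = cursor
            for rr in range(rlo, rhi + 1):
                for cc in range(clo, chi + 1):
                    buf[cursor] = tape[rr, cc]
                    cursor += 1
        else:
            out_dims[i, 0] = -1
        for rr in range(rlo, rhi + 1):
            for cc in range(clo, chi + 1):
                tape[rr, cc] = 0
    return n_mach, cursor


def _decode_machine_indices(indices: np.ndarray, base: int, n_cells: int) -> np.ndarray:
    tables = np.empty((indices.size, n_cells), dtype=np.int64)
    x = indices.copy()
    for j in range(n_cells):
        tables[:, j] = x % base
        x //= base
    return tables


_DIGIT = np.array([str(d) for d in range(10)])


def _collect_1d(tables: np.ndarray, space: MachineSpace, counts: Counter) -> int:
    max_len = 2 * space.step_cap + 3
    out_buf = np.zeros((tables.shape[0], max_len), dtype=np.uint8)
    out_len = np.zeros(tables.shape[0], dtype=np.int64)
    _run_chunk_1d(tables, space.n_states, space.n_symbols, space.step_cap, out_buf, out_len)
    halting = 0
    for i in range(tables.shape[0]):
        n = out_len[i]
        if n < 0:
            continue
        halting += 1
        counts[_canonical_key_1d(out_buf[i, :n])] += 1
    return halting


def _collect_2d(tables: np.ndarray, space: MachineSpace, counts: Counter) -> int:
    n_mach = tables.shape[0]
    # worst-case single rectangle is ~(cap/2+1)^2 cells; typical outputs are tiny
    buf = np.zeros(max(n_mach * 64, (space.step_cap // 2 + 2) ** 2 * 2), dtype=np.uint8)
    offsets = np.zeros(n_mach, dtype=np.int64)
    dims = np.zeros((n_mach, 2), dtype=np.int64)
    halting = 0
    start = 0
    while start < n_mach:
        stop, _ = _run_chunk_2d(
            tables, space.n_states, space.n_symbols, space.step_cap, buf, offsets, dims, start
        )
        for i in range(start, stop):
            nr, nc = dims[i]
            if nr < 0:
                continue
            halting += 1
            rect = buf[offsets[i] : offsets[i] + nr * nc].reshape(nr, nc)
            counts[_canonical_key_2d(rect)] += 1
        start = stop
    return halting


def _check_exhaustive(space: MachineSpace) -> None:
    if space.mode != "exhaustive":
        raise ValueError("enumerate_space requires exhaustive mode")
    if space.n_machines > ENUMERATION_BUDGET:
        raise ValueError(
            f"refusing exhaustive enumeration of {space.n_machines} machines "
            f"(budget {ENUMERATION_BUDGET}); use sampled mode"
        )
    known = BUSY_BEAVER_STEPS.get((space.n_states, space.n_symbols))
    if space.dimension == 1 and known is not None and space.step_cap < known:
        warnings.warn(
            f"step_cap={space.step_cap} is below the known busy-beaver bound "
            f"{known} for ({space.n_states},{space.n_symbols}); some halting "
            "machines will be excluded",
            stacklevel=3,
        )


def enumerate_space(space: MachineSpace, chunk_size: int = 1 << 16) -> FrequencyDistribution:
    """Exhaustively enumerate a machine space and count canonical outputs."""
    _check_exhaustive(space)
    counts: Counter[str] = Counter()
    total = 0
    collect = _collect_1d if space.dimension == 1 else _collect_2d
    for start in range(0, space.n_machines, chunk_size):
        idx = np.arange(start, min(start + chunk_size, space.n_machines), dtype=np.int64)
        tables = _decode_machine_indices(idx, space.n_entry_options, space.n_cells)
        total += collect(tables, space, counts)
    return FrequencyDistribution(space, dict(counts), total)


def sample_space(space: MachineSpace, chunk_size: int = 1 << 16) -> FrequencyDistribution:
    """Monte-Carlo estimate of the output-frequency distribution.

    Machines are drawn uniformly with replacement: each transition-table
    cell is drawn uniformly over its entry options. Reproducible by
    ``space.seed``.
    """
    if space.mode != "sampled":
        raise ValueError("sample_space requires sampled mode")
    rng = np.random.default_rng(space.seed)
    counts: Counter[str] = Counter()
    total = 0
    collect = _collect_1d if space.dimension == 1 else _collect_2d
    remaining = space.sample_size
    while remaining > 0:
        m = min(chunk_size, remaining)
        tables = rng.integers(0, space.n_entry_options, size=(m, space.n_cells))
        total += collect(tables, space, counts)
        remaining -= m
    return FrequencyDistribution(space, dict(counts), total)
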