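"""Coding-theorem complexity tables and block decomposition.

The coding theorem of algorithmic probability links the probability m(s)
that a universal machine produces string s to its Kolmogorov complexity,
K(s) ~ -log2 m(s).  Here m(s) is approximated by the output frequency of s
among the halting machines of a small enumerated (or sampled) machine
space, giving the Coding Theorem Method (CTM) estimate

    K(s) = -log2( count(s) / total_halting )   [bits]

Strings absent from a table receive a fallback value strictly above the
largest covered K (max covered K + ``fallback_margin``), which preserves
the frequency ordering while keeping every score defined at desk scale.

Objects larger than the machine outputs in a table are scored with the
Block Decomposition Method (BDM): partition into non-overlapping blocks and
sum, over *distinct* blocks, K(block) + log2(multiplicity of that block).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .machines import FrequencyDistribution, MachineSpace, canonical_relabel

__all__ = ["CTMTable", "coding_theorem", "bdm", "write_table", "read_table"]


@dataclass
class CTMTable:
    """CTM complexity estimates for the canonical outputs of a machine space."""

    source: dict
    counts: dict[str, int]
    total_halting: int
    complexity: dict[str, float]
    fallback_margin: float
    fallback_value: float
    #: cached (mu, sigma) string-space moments keyed by "alphabet:length" etc.
    moments_cache: dict[str, tuple[float, float]] = field(default_factory=dict)

    def lookup(self, key: str) -> tuple[float, bool]:
        """K in bits for a canonical key; flag is True when the fallback fired."""
        k = self.complexity.get(key)
        if k is None:
            return self.fallback_value, True
        return k, False

    def covered_keys(self, length: int | None = None):
        if length is None:
            return self.complexity.keys()
        return [s for s in self.complexity if len(s.replace("/", "")) == length]

    @property
    def fallback_rule(self) -> str:
        return f"max covered K + {self.fallback_margin} bits = {self.fallback_value:.6f}"


def coding_theorem(dist: FrequencyDistribution, fallback_margin: float = 1.0) -> CTMTable:
    """Turn an output-frequency distribution into a CTM complexity table."""
    if dist.total_halting < 1 or not dist.counts:
        raise ValueError("empty distribution: no halting machines")
    total = dist.total_halting
    complexity = {s: -math.log2(c / total) for s, c in dist.counts.items()}
    fallback = max(complexity.values()) + fallback_margin
    return CTMTable(
        source=dist.space.describe(),
        counts=dict(dist.counts),
        total_halting=total,
        complexity=complexity,
        fallback_margin=fallback_margin,
        fallback_value=fallback,
    )


def _canonical_key(block) -> str:
    if isinstance(block, str):
        return "".join(str(v) for v in canonical_relabel(int(ch) for ch in block))
    arr = np.asarray(block)
    if arr.ndim == 1:
        return "".join(str(v) for v in canonical_relabel(int(v) for v in arr))
    flat = canonical_relabel(int(v) for v in arr.ravel())
    nc = arr.shape[1]
    return "/".join(
        "".join(str(v) for v in flat[i : i + nc]) for i in range(0, len(flat), nc)
    )


def _blocks_1d(seq, block_len: int):
    for i in range(0, len(seq), block_len):
        yield tuple(seq[i : i + block_len])


def _blocks_2d(arr: np.ndarray, shape: tuple[int, int]):
    br, bc = shape
    for r in range(0, arr.shape[0], br):
        for c in range(0, arr.shape[1], bc):
            yield tuple(map(tuple, arr[r : r + br, c : c + bc]))


def bdm(
    obj,
    base_table: CTMTable,
    block_shape,
    with_flag: bool = False,
):
    """Block-decomposition complexity estimate in bits.

    ``obj`` is a 1-D sequence (string of digits or int sequence) with integer
    ``block_shape``, or a 2-D integer array with ``block_shape = (rows,
    cols)``.  Blocks are non-overlapping; remainder blocks at the edges keep
    their natural smaller size.  Distinct blocks are counted *as produced*
    (not canonicalized) — relabeling the alphabet permutes raw blocks
    bijectively, so the result is invariant under symbol permutation.
    """
    if isinstance(obj, str):
        seq = [int(ch) for ch in obj]
    else:
        seq = np.asarray(obj)
    if len(seq) == 0:
        raise ValueError("empty input")
    if isinstance(seq, np.ndarray) and seq.ndim == 2:
        br, bc = block_shape
        if br > seq.shape[0] or bc > seq.shape[1]:
            raise ValueError("block_shape larger than the input")
        blocks = list(_blocks_2d(seq, (br, bc)))
    else:
        block_len = int(block_shape)
        if block_len > len(seq):
            raise ValueError("block_shape larger than the input")
        blocks = list(_blocks_1d(list(seq), block_len))

    mult: dict = {}
    for b in blocks:
        mult[b] = mult.get(b, 0) + 1
    total = 0.0
    fallback_used = False
    for b, m in mult.items():
        k, fb = base_table.lookup(_canonical_key(np.asarray(b)))
        fallback_used |= fb
        total += k + math.log2(m)
    if with_flag:
        return total, fallback_used
    return total


# ---------------------------------------------------------------------------
# Table files: TSV (canonical_string, count, K_bits) + JSON sidecar with the
# machine-space provenance, fallback rule and cached normalization moments.
# ---------------------------------------------------------------------------


def write_table(table: CTMTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("canonical_string\tcount\tK_bits\n")
        for s in sorted(table.complexity, key=lambda s: (len(s), s)):
            fh.write(f"{s}\t{table.counts[s]}\t{table.complexity[s]:.12g}\n")
    sidecar = {
        "space": table.source,
        "total_halting": table.total_halting,
        "fallback_margin": table.fallback_margin,
        "fallback_value": table.fallback_value,
        "fallback_rule": table.fallback_rule,
        "moments_cache": {k: list(v) for k, v in table.moments_cache.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_table(path: str | Path) -> CTMTable:
    path = Path(path)
    counts: dict[str, int] = {}
    complexity: dict[str, float] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["canonical_string", "count", "K_bits"]:
            raise ValueError(f"{path}: not a CTM table file (header {header})")
        for line in fh:
            s, c, k = line.rstrip("\n").split("\t")
            counts[s] = int(c)
            complexity[s] = float(k)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
        space = side.get("space", {})
        total = side.get("total_halting", sum(counts.values()))
        margin = side.get("fallback_margin", 1.0)
        fallback = side.get("fallback_value", max(complexity.values()) + margin)
        cache = {k: tuple(v) for k, v in side.get("moments_cache", {}).items()}
    else:
        space, total, margin = {}, sum(counts.values()), 1.0
        fallback = max(complexity.values()) + margin
        cache = {}
    return CTMTable(
        source=space,
        counts=counts,
        total_halting=total,
        complexity=complexity,
        fallback_margin=margin,
        fallback_value=fallback,
        moments_cache=cache,
    )
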