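"""From raw task responses to normalized complexity scores.

A response's complexity K (bits) is estimated from the task's CTM table —
directly for strings the table covers, through block decomposition for the
longer task strings.  K is then standardized against the *full* response
space of the task: with mu and sigma the mean and standard deviation of K
over all ``alphabet_size ** length`` possible strings,

    z = (K - mu) / sigma,

so z = 0 is the mean complexity of all possible strings of that length and
alphabet, and z is comparable across tasks.

The full-space moments are never computed by enumerating every string:
complexity is invariant under relabeling of the alphabet, so the space is
iterated by canonical symbol-order classes (restricted growth strings) and
each class with d distinct symbols is weighted by its multiplicity
k!/(k-d)!.  For the circles task this reduces 9**10 strings to ~116 000
classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .ctm import CTMTable, bdm
from .machines import canonical_relabel
from .tasks import TASKS, TaskSpec

__all__ = [
    "NormalizedScore",
    "canonical_form",
    "restricted_growth_strings",
    "falling_factorial",
    "response_complexity",
    "string_space_moments",
    "score_response",
    "mean_complexity",
    "first_order_entropy",
    "score_cohort",
]


@dataclass(frozen=True)
class NormalizedScore:
    participant_id: str
    task_id: str
    K_raw: float  # bits
    z: float  # dimensionless, standardized over the full string space
    CT: float  # seconds (NaN when not recorded)
    fallback_used: bool


def canonical_form(sequence, alphabet_size: int):
    """Relabel symbols by first occurrence; returns the input's type.

    ``"221212"`` over a 3-letter alphabet becomes ``"001010"``.  Idempotent;
    raises on symbols outside ``range(alphabet_size)``, naming the position.
    """
    as_str = isinstance(sequence, str)
    symbols = [int(ch) for ch in sequence] if as_str else [int(v) for v in sequence]
    for i, s in enumerate(symbols):
        if not 0 <= s < alphabet_size:
            raise ValueError(
                f"symbol {s} at position {i} outside alphabet of size {alphabet_size}"
            )
    canon = canonical_relabel(symbols)
    if as_str:
        return "".join(str(v) for v in canon)
    return list(canon)


def restricted_growth_strings(
    length: int, max_blocks: int
) -> Iterator[tuple[tuple[int, ...], int]]:
    """Yield (canonical string, #distinct symbols) for every canonical class.

    A canonical symbol-order string is exactly a restricted growth string:
    each position holds either a previously used symbol or the next unused
    one.  ``max_blocks`` caps the number of distinct symbols (the alphabet
    size).
    """
    seq = [0] * length

    def rec(i: int, used: int):
        if i == length:
            yield tuple(seq), used
            return
        top = used + 1 if used < max_blocks else used
        for v in range(top):
            seq[i] = v
            yield from rec(i + 1, max(used, v + 1))

    if length == 0:
        return
    yield from rec(0, 0)


def falling_factorial(k: int, d: int) -> int:
    """k * (k-1) * ... * (k-d+1): strings per canonical class with d symbols."""
    out = 1
    for j in range(d):
        out *= k - j
    return out


def response_complexity(response, spec: TaskSpec, table: CTMTable) -> tuple[float, bool]:
    """Estimated K (bits) of one response, and whether the fallback fired."""
    if spec.dimension == 2:
        if isinstance(response, str):
            if len(response) != spec.length:
                raise ValueError(
                    f"{spec.task_id}: expected {spec.length} cells, got {len(response)}"
                )
            arr = np.array([int(ch) for ch in response]).reshape(spec.shape)
        else:
            arr = np.asarray(response).reshape(spec.shape)
        if arr.min() < 0 or arr.max() >= spec.alphabet_size:
            raise ValueError(
                f"{spec.task_id}: cell values must lie in [0, {spec.alphabet_size})"
            )
        return bdm(arr, table, spec.block_shape, with_flag=True)
    seq = canonical_form(response, spec.alphabet_size)
    if len(seq) != spec.length:
        raise ValueError(f"{spec.task_id}: expected length {spec.length}, got {len(seq)}")
    key = seq if isinstance(seq, str) else "".join(map(str, seq))
    if key in table.complexity:
        return table.complexity[key], False
    return bdm(key, table, spec.block_shape, with_flag=True)


def string_space_moments(spec: TaskSpec, table: CTMTable) -> tuple[float, float]:
    """Exact mean and SD of K over all alphabet**length strings of a task.

    Iterates canonical classes and weights each by its multiplicity; the
    result is cached on the table, keyed by the scoring configuration.
    """
    cache_key = f"{spec.task_id}:{spec.alphabet_size}^{spec.length}:blocks={spec.block_shape}"
    if cache_key in table.moments_cache:
        return table.moments_cache[cache_key]
    k = spec.alphabet_size
    total_w = 0
    s1 = []
    s2 = []
    for canon, d in restricted_growth_strings(spec.length, min(k, spec.length)):
        w = falling_factorial(k, d)
        key = "".join(map(str, canon))
        kval, _ = response_complexity(key, spec, table)
        total_w += w
        s1.append(w * kval)
        s2.append(w * kval * kval)
    assert total_w == spec.n_strings
    mu = math.fsum(s1) / total_w
    var = math.fsum(s2) / total_w - mu * mu
    if var <= 0:
        raise ValueError(
            f"{spec.task_id}: degenerate table — K is constant over the string space"
        )
    sigma = math.sqrt(var)
    table.moments_cache[cache_key] = (mu, sigma)
    return mu, sigma


def score_response(
    response,
    spec: TaskSpec,
    table: CTMTable,
    participant_id: str = "",
    ct: float = float("nan"),
) -> NormalizedScore:
    """Normalized complexity of one response (permutation-invariant, pure)."""
    if response is None or (isinstance(response, str) and response == ""):
        raise ValueError(f"{spec.task_id}: empty response")
    k_raw, fallback = response_complexity(response, spec, table)
    mu, sigma = string_space_moments(spec, table)
    return NormalizedScore(
        participant_id=participant_id,
        task_id=spec.task_id,
        K_raw=k_raw,
        z=(k_raw - mu) / sigma,
        CT=ct,
        fallback_used=fallback,
    )


def mean_complexity(z_values: Iterable[float]) -> tuple[float, int]:
    """Mean normalized complexity over available tasks; (NaN, 0) when none."""
    vals = [v for v in z_values if v is not None and not math.isnan(v)]
    if not vals:
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)


def first_order_entropy(sequence: Sequence | str, alphabet_size: int) -> float:
    """Shannon entropy (bits) of the empirical symbol distribution.

    A purely statistical comparator: it is blind to algorithmic structure —
    the strictly alternating string 0101... attains the maximal 1 bit.
    """
    symbols = [int(ch) for ch in sequence] if isinstance(sequence, str) else list(sequence)
    if not symbols:
        raise ValueError("empty sequence")
    counts = np.bincount(symbols, minlength=alphabet_size)
    p = counts[counts > 0] / len(symbols)
    return float(-np.sum(p * np.log2(p)))


def score_cohort(cohort, tables: dict[str, CTMTable] | None = None):
    """Score every complete response of a cohort table.

    ``cohort`` is a DataFrame in the cohort CSV layout (see
    :mod:`rigc.cohort`).  Returns a wide DataFrame with one row per
    participant: demographics, per-task ``z_<task>`` / ``ct_<task>`` /
    ``fallback_<task>``, ``mean_z`` (mean of available task z scores),
    ``n_tasks`` and ``total_ct``.
    """
    import pandas as pd

    if tables is None:
        from .tables import table_for_task

        tables = {tid: table_for_task(tid) for tid in TASKS}
    rows = []
    demo_cols = [
        c
        for c in ("participant_id", "age", "sex", "education", "field", "paranormal_belief")
        if c in cohort.columns
    ]
    for _, row in cohort.iterrows():
        rec = {c: row[c] for c in demo_cols}
        zs = []
        cts = []
        for tid, spec in TASKS.items():
            resp = row.get(f"{tid}_response")
            ct = row.get(f"{tid}_ct_seconds", float("nan"))
            if resp is None or (isinstance(resp, float) and math.isnan(resp)) or resp == "":
                rec[f"z_{tid}"] = float("nan")
                rec[f"k_{tid}"] = float("nan")
                rec[f"ct_{tid}"] = float("nan")
                rec[f"fallback_{tid}"] = False
                continue
            score = score_response(str(resp), spec, tables[tid], ct=float(ct))
            rec[f"z_{tid}"] = score.z
            rec[f"k_{tid}"] = score.K_raw
            rec[f"ct_{tid}"] = score.CT
            rec[f"fallback_{tid}"] = score.fallback_used
            zs.append(score.z)
            cts.append(score.CT)
        rec["mean_z"], rec["n_tasks"] = mean_complexity(zs)
        rec["total_ct"] = float(np.sum(cts)) if cts else float("nan")
        rows.append(rec)
    return pd.DataFrame(rows)


_DEMO_COLS = ("participant_id", "age", "sex", "education", "field", "paranormal_belief")


def scores_to_long(wide):
    """Wide per-participant scores -> one row per (participant, task)."""
    import pandas as pd

    demo = [c for c in _DEMO_COLS if c in wide.columns]
    rows = []
    for _, r in wide.iterrows():
        for tid in TASKS:
            if f"z_{tid}" not in wide.columns or math.isnan(r[f"z_{tid}"]):
                continue
            rec = {c: r[c] for c in demo}
            rec.update(
                task_id=tid,
                K_bits=r.get(f"k_{tid}", float("nan")),
                z=r[f"z_{tid}"],
                ct_seconds=r[f"ct_{tid}"],
                fallback_used=bool(r[f"fallback_{tid}"]),
            )
            rows.append(rec)
    return pd.DataFrame(rows)


def scores_to_wide(long):
    """Inverse of :func:`scores_to_long`, restoring mean_z / total_ct."""
    import pandas as pd

    demo = [c for c in _DEMO_COLS if c in long.columns]
    rows = []
    for pid, grp in long.groupby("participant_id", sort=False):
        rec = {c: grp.iloc[0][c] for c in demo}
        zs, cts = [], []
        for tid in TASKS:
            sub = grp[grp["task_id"] == tid]
            if len(sub):
                rec[f"z_{tid}"] = float(sub.iloc[0]["z"])
                rec[f"k_{tid}"] = float(sub.iloc[0]["K_bits"])
                rec[f"ct_{tid}"] = float(sub.iloc[0]["ct_seconds"])
                rec[f"fallback_{tid}"] = bool(sub.iloc[0]["fallback_used"])
                zs.append(rec[f"z_{tid}"])
                cts.append(rec[f"ct_{tid}"])
            else:
                rec[f"z_{tid}"] = rec[f"k_{tid}"] = rec[f"ct_{tid}"] = float("nan")
                rec[f"fallback_{tid}"] = False
        rec["mean_z"], rec["n_tasks"] = mean_complexity(zs)
        rec["total_ct"] = float(np.sum(cts)) if cts else float("nan")
        rows.append(rec)
    return pd.DataFrame(rows)
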