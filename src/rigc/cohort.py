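"""Synthetic cohorts with lifespan structure.

The generator emulates the statistical structure a lifespan RIG study
assumes, so the whole measurement chain can be exercised without any real
data:

* a cross-sectional sample of ages 4-91 (truncated normal, mean 37.72,
  SD 13.38) with a ~2:1 male:female split, age-capped education levels,
  a field of education for participants above 15, and a 1-6 paranormal
  belief rating;
* a latent *randomization ability* in [0, 1] that follows a lifespan curve
  peaking at 25, declining slowly to 60 and faster afterwards;
* response sequences produced by a Markov reweighting model of the classic
  randomization heuristics — repetition avoidance, alternation bias (binary
  tasks) and cycling (postponing re-use of a symbol until all alternatives
  have been used) — whose strength shrinks to zero as ability approaches 1
  (ability 1 = i.i.d. uniform responding);
* completion times that are lognormal around a U-shaped age curve (fastest
  near 25) with a multiplicative male speed factor;
* a small negative effect of paranormal belief on grid-task ability.

The bias model is generative glue, not a cognitive theory: it produces the
qualitative regularities the analysis must detect, with magnitudes chosen
so the simulated trajectories resemble the lifespan curves the package is
designed to estimate.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import truncnorm

from .tasks import TASK_ORDER, TASKS, TaskSpec

__all__ = [
    "BiasProfile",
    "LifespanCurve",
    "CovariateEffects",
    "Cohort",
    "sample_cohort",
    "generate_response",
    "generate_ct",
    "ct_median",
    "write_cohort",
    "read_cohort",
]

#: Table-2-style demographic marginals used by the sampler.
P_MALE = 2333 / (2333 + 1085)
EDUCATION_COUNTS = np.array([38, 83, 387, 621, 347, 1364, 538], dtype=float)
FIELD_LEVELS = ("humanities", "science", "other")
FIELD_COUNTS = np.array([609, 1684, 550], dtype=float)
#: Youngest age at which each education level (1..7) is attainable.
EDUCATION_MIN_AGE = np.array([0, 6, 11, 15, 18, 21, 24])

AGE_MEAN, AGE_SD, AGE_MIN, AGE_MAX = 37.72, 13.38, 4, 91


@dataclass(frozen=True)
class BiasProfile:
    """Randomization-heuristic strengths, scaled down as ability grows.

    The damping is concave (sqrt(1 - ability)): heuristic residue fades
    slowly at first — even competent randomizers keep mild repetition
    avoidance and alternation habits — and vanishes only at ability 1,
    where responding is exactly i.i.d. uniform.
    """

    repetition_avoidance: float = 0.95
    alternation_excess: float = 0.6
    cycling_strength: float = 0.85
    #: grid-specific habit: the tendency to repeat the previous row of the
    #: grid verbatim (spatial pattern perseveration / symmetry seeking)
    pattern_persistence: float = 0.55
    ability: float = 1.0

    def damp(self) -> float:
        return math.sqrt(1.0 - min(max(self.ability, 0.0), 1.0))

    def effective(self) -> tuple[float, float, float]:
        d = self.damp()
        return (
            self.repetition_avoidance * d,
            self.alternation_excess * d,
            self.cycling_strength * d,
        )


@dataclass(frozen=True)
class LifespanCurve:
    """Expected randomization ability as a function of age.

    A smooth (monotone-segment PCHIP) curve through four knots derived from
    the slopes: rising through childhood to a maximum at ``peak_age``,
    declining gently until ``plateau_end`` and faster afterwards
    (|late_slope| > |adult_slope|).  Ability units are arbitrary in [0, 1].
    """

    peak_age: float = 25.0
    plateau_end: float = 60.0
    peak_ability: float = 0.85
    child_slope: float = 0.02  # ability units / year, average over ages 4 -> peak
    adult_slope: float = 0.010  # peak -> plateau_end
    late_slope: float = 0.022  # plateau_end -> 91
    #: ability still to be gained in the last ~9 years before the peak:
    #: childhood gains are rapid and decelerate into the summit, so the
    #: curve is locally rounded (roughly symmetric) around peak_age.
    presummit_gap: float = 0.06
    noise_sd: float = 0.08

    def __post_init__(self) -> None:
        if abs(self.late_slope) <= abs(self.adult_slope):
            raise ValueError("late decline must be steeper than the adult decline")

    def _interpolator(self) -> PchipInterpolator:
        adolescent_age = self.peak_age - 9.0
        ages = [AGE_MIN, adolescent_age, self.peak_age, self.plateau_end, AGE_MAX]
        vals = [
            self.peak_ability - self.child_slope * (self.peak_age - AGE_MIN),
            self.peak_ability - self.presummit_gap,
            self.peak_ability,
            self.peak_ability - self.adult_slope * (self.plateau_end - self.peak_age),
        ]
        vals.append(vals[3] - self.late_slope * (AGE_MAX - self.plateau_end))
        return PchipInterpolator(ages, vals)

    def expected_ability(self, age):
        """Noise-free mean ability at the given age(s), clipped to [0, 1]."""
        return np.clip(self._interpolator()(age), 0.0, 1.0)


@dataclass(frozen=True)
class CovariateEffects:
    """Demographic effects injected into the generated data."""

    male_ct_factor: float = 0.93  # multiplicative male speed-up on CT medians
    belief_grid_ability: float = 0.01  # ability lost per paranormal-belief point (grid)
    ct_sigma: float = 0.35  # lognormal shape of completion times
    ct_age_gain: float = 0.8  # relative CT slow-down across the age range
    ct_base: dict = field(
        default_factory=lambda: {
            "coin": 22.0,
            "card": 18.0,
            "die": 25.0,
            "circles": 20.0,
            "grid": 15.0,
        }
    )


@dataclass
class Cohort:
    """Participant table plus the full generator configuration."""

    table: pd.DataFrame
    config: dict


def generate_response(spec: TaskSpec, profile: BiasProfile, rng):
    """One simulated response: a digit string, or (grid string, clicks).

    Sequential sampling: at each position the next-symbol distribution is
    uniform, reweighted by the (1-ability)-scaled biases — the probability
    of an immediate repetition is multiplied by (1 - repetition avoidance);
    for binary alphabets the alternative to the previous symbol is boosted
    by (1 + alternation excess); while unused symbols remain, used symbols
    are down-weighted by (1 - cycling strength).  The grid is generated as
    nine sequential binary cells (row-major) with one extra spatial habit —
    each later row repeats the previous row verbatim with probability
    (pattern persistence x damping) — plus a click count: one click per
    black cell and a geometric number of extra toggle pairs.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rep, alt, cyc = profile.effective()
    row_repeat = profile.pattern_persistence * profile.damp() if spec.dimension == 2 else 0.0
    ncol = spec.shape[1] if spec.dimension == 2 else 0
    k = spec.alphabet_size
    length = spec.length
    used: set[int] = set()
    prev = -1
    out: list[int] = []
    while len(out) < length:
        i = len(out)
        if row_repeat and i >= ncol and i % ncol == 0 and rng.random() < row_repeat:
            row = out[i - ncol : i]
            out.extend(row)
            used.update(row)
            prev = row[-1]
            continue
        w = [1.0] * k
        if prev >= 0:
            w[prev] *= 1.0 - rep
            if k == 2:
                w[1 - prev] *= 1.0 + alt
        if 0 < len(used) < k:
            for s in used:
                w[s] *= 1.0 - cyc
        total = sum(w)
        if total <= 0:  # fully suppressed: fall back to uniform over the rest
            w = [1.0] * k
            total = float(k)
        r = rng.random() * total
        acc = 0.0
        sym = k - 1
        for s in range(k):
            acc += w[s]
            if r < acc:
                sym = s
                break
        out.append(sym)
        used.add(sym)
        prev = sym
    response = "".join(str(s) for s in out)
    if spec.dimension == 2:
        clicks = out.count(1) + 2 * int(rng.geometric(0.3) - 1)
        return response, clicks
    return response


def ct_median(age: float, sex: str, task_id: str, effects: CovariateEffects) -> float:
    """Median completion time (s): U-shaped in age, scaled for male speed."""
    base = effects.ct_base[task_id]
    m = base * (1.0 + effects.ct_age_gain * ((age - 25.0) / 35.0) ** 2)
    if sex == "male":
        m *= effects.male_ct_factor
    return m


def generate_ct(age, sex, task_id, rng, effects: CovariateEffects | None = None) -> float:
    """Lognormal completion-time draw around the age/sex median (seconds)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    effects = effects or CovariateEffects()
    return ct_median(age, sex, task_id, effects) * math.exp(
        effects.ct_sigma * rng.standard_normal()
    )


def sample_cohort(
    n: int,
    curve: LifespanCurve | None = None,
    effects: CovariateEffects | None = None,
    biases: BiasProfile | None = None,
    seed: int | None = None,
    tasks: list[str] | None = None,
) -> Cohort:
    """Draw a full synthetic cohort, reproducible from ``seed``.

    ``tasks`` restricts response generation to a subset of the five tasks
    (demographics are always drawn identically for a given seed).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    curve = curve or LifespanCurve()
    effects = effects or CovariateEffects()
    biases = biases or BiasProfile()
    tasks = TASK_ORDER if tasks is None else [t for t in TASK_ORDER if t in tasks]

    ss = np.random.SeedSequence(seed)
    demo_rng, resp_rng, ct_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    a, b = (AGE_MIN - AGE_MEAN) / AGE_SD, (AGE_MAX - AGE_MEAN) / AGE_SD
    ages = np.clip(
        np.rint(truncnorm.rvs(a, b, loc=AGE_MEAN, scale=AGE_SD, size=n, random_state=demo_rng)),
        AGE_MIN,
        AGE_MAX,
    ).astype(int)
    sexes = np.where(demo_rng.random(n) < P_MALE, "male", "female")
    beliefs = demo_rng.integers(1, 7, size=n)

    max_level = np.searchsorted(EDUCATION_MIN_AGE, ages, side="right")  # 1..7
    education = np.empty(n, dtype=int)
    for i in range(n):
        p = EDUCATION_COUNTS[: max_level[i]]
        education[i] = demo_rng.choice(max_level[i], p=p / p.sum()) + 1
    fields = np.where(
        ages > 15,
        demo_rng.choice(FIELD_LEVELS, size=n, p=FIELD_COUNTS / FIELD_COUNTS.sum()),
        "",
    )

    ability = np.clip(
        curve.expected_ability(ages) + demo_rng.standard_normal(n) * curve.noise_sd,
        0.0,
        1.0,
    )

    rows = []
    for i in range(n):
        rec: dict = {
            "participant_id": f"p{i:05d}",
            "age": int(ages[i]),
            "sex": str(sexes[i]),
            "education": int(education[i]),
            "field": str(fields[i]),
            "paranormal_belief": int(beliefs[i]),
        }
        for tid in tasks:
            spec = TASKS[tid]
            ab = ability[i]
            if tid == "grid":
                ab = max(0.0, ab - effects.belief_grid_ability * beliefs[i])
            profile = BiasProfile(
                biases.repetition_avoidance,
                biases.alternation_excess,
                biases.cycling_strength,
                ability=ab,
            )
            resp = generate_response(spec, profile, resp_rng)
            if tid == "grid":
                rec["grid_response"], rec["grid_clicks"] = resp
            else:
                rec[f"{tid}_response"] = resp
            rec[f"{tid}_ct_seconds"] = round(
                generate_ct(ages[i], sexes[i], tid, ct_rng, effects), 3
            )
        rows.append(rec)

    config = {
        "n": n,
        "seed": seed,
        "tasks": tasks,
        "curve": asdict(curve),
        "effects": asdict(effects),
        "biases": {
            "repetition_avoidance": biases.repetition_avoidance,
            "alternation_excess": biases.alternation_excess,
            "cycling_strength": biases.cycling_strength,
        },
    }
    return Cohort(pd.DataFrame(rows), config)


def write_cohort(cohort: Cohort, path) -> None:
    """CSV of the participant table + JSON sidecar with the generator config."""
    import json
    from pathlib import Path

    path = Path(path)
    cohort.table.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(cohort.config, indent=1))


def read_cohort(path) -> Cohort:
    import json
    from pathlib import Path

    path = Path(path)
    dtypes = {f"{t}_response": str for t in TASK_ORDER}
    dtypes["grid_response"] = str
    table = pd.read_csv(path, dtype=dtypes, keep_default_na=False, na_values=[""])
    if "field" in table.columns:
        table["field"] = table["field"].fillna("")
    sidecar = path.with_suffix(path.suffix + ".json")
    config = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Cohort(table, config)
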