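"""Synthetic paired manual/scan measurement cohorts.

The study data this package analyses — children aged 6-59 months measured
both by manual anthropometry and by a 3D-scanning device — were never
deposited, so the generator here emulates their statistical structure:

* truth sampled on the z-score scale and inverted through the LMS reference,
* manual measurements with small unbiased noise plus terminal-digit rounding
  (anthropometrists heap on 0.5-cm grid marks),
* scan measurements with additive device bias, a size-proportional error
  component (larger children, larger errors), team-specific noise levels,
  occasional gross outliers (a caregiver in the frame read as the child, or
  near-zero device-failure readings),
* team-dependent missingness and caregiver refusal of the scan,
* identifier corruption: a fraction of children have their scan-side IDs
  pairwise swapped, producing the age/sex/weight discordances the linkage
  stage must flag.

Randomness is fully deterministic under (config, seed): each child draws
from a substream keyed by (seed, stage, child index), so enlarging the
cohort leaves existing children's records untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .growth_reference import (
    GrowthReference,
    Indicator,
    DAYS_PER_MONTH,
    synthetic_reference,
)

__all__ = [
    "CohortConfig",
    "generate_truth",
    "apply_manual_process",
    "apply_scan_process",
    "corrupt_identifiers",
    "generate_differences",
    "simulate_cohort",
    "write_cohort",
    "load_cohort",
]

MEASURES = ("stature", "muac")

# substream tags — never reorder (would silently change every fixture)
_TRUTH, _MANUAL, _SCAN, _SWAP = 1, 2, 3, 4


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


@dataclass
class CohortConfig:
    """All generator parameters.

    Defaults emulate the published field-study conditions: 539 children in
    six teams, ~10% scan refusal, strongly team-dependent scan loss, device
    bias of about -0.5 cm (stature) and +0.7 cm (MUAC), team noise levels
    spanning the reported per-team limits of agreement, 5% gross-outlier
    contamination, and a quarter of children with swapped scan IDs.
    Per-measure dictionaries are keyed "stature"/"muac"; per-team sequences
    are indexed team 1..n_teams.
    """

    n_children: int = 539
    n_teams: int = 6
    age_range_months: tuple[float, float] = (6.0, 59.0)
    sex_ratio: float = 0.5  # proportion male
    z_mean: Mapping[str, float] = field(default_factory=lambda: {"whz": -1.0, "haz": -0.9})
    z_sd: Mapping[str, float] = field(default_factory=lambda: {"whz": 1.1, "haz": 1.25})
    muac_mean_cm: float = 14.0
    muac_sd_cm: float = 1.2
    manual_noise_sd_cm: Mapping[str, float] = field(
        default_factory=lambda: {"stature": 0.4, "muac": 0.2}
    )
    weight_noise_sd_kg: float = 0.05
    digit_pref_prob: Mapping[str, float] = field(
        default_factory=lambda: {"stature": 0.2, "muac": 0.3}
    )
    digit_pref_grid_cm: float = 0.5
    scan_bias_cm: Mapping[str, float] = field(
        default_factory=lambda: {"stature": -0.5, "muac": 0.72}
    )
    scan_slope: Mapping[str, float] = field(
        default_factory=lambda: {"stature": 0.3, "muac": 0.5}
    )
    scan_noise_sd_cm: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "stature": (3.6, 5.1, 4.0, 6.0, 10.0, 6.0),
            "muac": (1.7, 1.9, 1.5, 1.9, 2.8, 1.9),
        }
    )
    outlier_prob: float = 0.05
    outlier_model: str = "adult-contaminant"  # or "near-zero"
    sessions_probs: tuple[float, ...] = (0.88, 0.12)  # P(1 session), P(2), ...
    missingness_prob: tuple[float, ...] = (0.09, 0.41, 0.53, 0.84, 0.22, 0.96)
    refusal_prob: float = 0.104
    mismatch_rate: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        if self.n_teams < 1:
            raise ValueError("n_teams must be >= 1")
        lo, hi = self.age_range_months
        if not (0 < lo <= hi):
            raise ValueError(f"bad age range {self.age_range_months}")
        for name, p in [
            ("sex_ratio", self.sex_ratio),
            ("outlier_prob", self.outlier_prob),
            ("refusal_prob", self.refusal_prob),
            ("mismatch_rate", self.mismatch_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for m in MEASURES:
            if self.manual_noise_sd_cm[m] < 0:
                raise ValueError("manual noise SD must be >= 0")
            if not 0.0 <= self.digit_pref_prob[m] <= 1.0:
                raise ValueError("digit_pref_prob must be in [0, 1]")
            if any(s < 0 for s in self.scan_noise_sd_cm[m]):
                raise ValueError("scan noise SDs must be >= 0")
            if len(self.scan_noise_sd_cm[m]) < self.n_teams:
                raise ValueError(f"scan_noise_sd_cm[{m!r}] shorter than n_teams")
        if len(self.missingness_prob) < self.n_teams:
            raise ValueError("missingness_prob shorter than n_teams")
        if any(not 0.0 <= p <= 1.0 for p in self.missingness_prob):
            raise ValueError("missingness probabilities must be in [0, 1]")
        if self.outlier_model not in ("adult-contaminant", "near-zero"):
            raise ValueError(f"unknown outlier_model {self.outlier_model!r}")
        sp = np.asarray(self.sessions_probs, float)
        if sp.size == 0 or (sp < 0).any() or not np.isclose(sp.sum(), 1.0):
            raise ValueError("sessions_probs must be nonnegative and sum to 1")
        if self.muac_sd_cm < 0 or self.weight_noise_sd_kg < 0:
            raise ValueError("SDs must be >= 0")

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def noise_free(cls, n_children: int = 50, n_teams: int = 2, seed: int = 0, **kw) -> "CohortConfig":
        """An identity-device configuration: scans reproduce truth exactly."""
        zeros = {"stature": 0.0, "muac": 0.0}
        base = dict(
            n_children=n_children,
            n_teams=n_teams,
            manual_noise_sd_cm=dict(zeros),
            weight_noise_sd_kg=0.0,
            digit_pref_prob=dict(zeros),
            scan_bias_cm=dict(zeros),
            scan_slope=dict(zeros),
            scan_noise_sd_cm={m: (0.0,) * n_teams for m in MEASURES},
            outlier_prob=0.0,
            sessions_probs=(1.0,),
            missingness_prob=(0.0,) * n_teams,
            refusal_prob=0.0,
            mismatch_rate=0.0,
            seed=seed,
        )
        base.update(kw)
        return cls(**base)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("age_range_months", "sessions_probs", "missingness_prob"):
            if key in d:
                d[key] = tuple(d[key])
        if "scan_noise_sd_cm" in d:
            d["scan_noise_sd_cm"] = {m: tuple(v) for m, v in d["scan_noise_sd_cm"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range_months"] = list(d["age_range_months"])
        d["sessions_probs"] = list(d["sessions_probs"])
        d["missingness_prob"] = list(d["missingness_prob"])
        d["scan_noise_sd_cm"] = {m: list(v) for m, v in d["scan_noise_sd_cm"].items()}
        return d


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

def _check_coverage(config: CohortConfig, reference: GrowthReference) -> None:
    lo_m, hi_m = config.age_range_months
    for ind in (Indicator.STATURE_FOR_AGE, Indicator.WEIGHT_FOR_AGE):
        for sex in ("female", "male"):
            klo, khi = reference.coverage(ind, sex)
            if lo_m * DAYS_PER_MONTH < klo or hi_m * DAYS_PER_MONTH > khi:
                raise ValueError(
                    f"reference {ind.value} ({sex}) does not cover ages "
                    f"{lo_m:g}-{hi_m:g} months"
                )


def generate_truth(config: CohortConfig, reference: GrowthReference | None = None) -> pd.DataFrame:
    """Sample the true, error-free cohort.

    Each child's HAZ is drawn Normal(z_mean['haz'], z_sd['haz']) and inverted
    through the stature-for-age reference to a true stature; WHZ likewise
    through weight-for-stature at that stature to a true weight.  MUAC truth
    is Normal(muac_mean_cm, muac_sd_cm) — MUAC is classified on raw cm and
    needs no reference.  Teams are assigned round-robin.
    """
    if reference is None:
        reference = synthetic_reference()
    _check_coverage(config, reference)
    lo, hi = config.age_range_months
    rows = []
    for i in range(config.n_children):
        rng = _rng(config.seed, _TRUTH, i)
        age = float(rng.uniform(lo, hi))
        sex = "male" if rng.random() < config.sex_ratio else "female"
        team = (i % config.n_teams) + 1
        z_haz = config.z_mean["haz"] + config.z_sd["haz"] * rng.standard_normal()
        stature = reference.invert(Indicator.STATURE_FOR_AGE, sex, age * DAYS_PER_MONTH, z_haz)
        if np.isnan(stature):
            raise ValueError(f"reference coverage gap at age {age:.2f} months")
        z_whz = config.z_mean["whz"] + config.z_sd["whz"] * rng.standard_normal()
        weight = reference.invert(Indicator.WEIGHT_FOR_STATURE, sex, stature, z_whz)
        if np.isnan(weight):
            raise ValueError(
                f"reference weight-for-stature coverage gap at stature {stature:.1f} cm"
            )
        muac = max(6.0, config.muac_mean_cm + config.muac_sd_cm * rng.standard_normal())
        rows.append(
            (f"C{i:04d}", team, sex, age, stature, muac, weight, z_haz, z_whz)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "child_id",
            "team",
            "sex",
            "age_months",
            "true_stature_cm",
            "true_muac_cm",
            "true_weight_kg",
            "z_haz",
            "z_whz",
        ],
    )


# ---------------------------------------------------------------------------
# Measurement processes
# ---------------------------------------------------------------------------

def _round_to_grid(value: float, grid: float) -> float:
    return float(np.round(value / grid) * grid)


def apply_manual_process(truth: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Manual anthropometry: small unbiased noise plus digit-preference rounding."""
    if len(truth) == 0:
        raise ValueError("truth cohort is empty")
    rows = []
    for i, row in enumerate(truth.itertuples(index=False)):
        rng = _rng(config.seed, _MANUAL, i)
        vals = {}
        for m, true_val in (("stature", row.true_stature_cm), ("muac", row.true_muac_cm)):
            v = true_val + config.manual_noise_sd_cm[m] * rng.standard_normal()
            if rng.random() < config.digit_pref_prob[m]:
                v = _round_to_grid(v, config.digit_pref_grid_cm)
            vals[m] = v
        weight = row.true_weight_kg + config.weight_noise_sd_kg * rng.standard_normal()
        rows.append(
            (row.child_id, row.team, row.sex, row.age_months, weight, vals["stature"], vals["muac"])
        )
    return pd.DataFrame(
        rows,
        columns=["child_id", "team", "sex", "age_months", "weight_kg", "stature_cm", "muac_cm"],
    )


def _contaminate(rng: np.random.Generator, model: str) -> tuple[float, float]:
    if model == "adult-contaminant":
        # caregiver in frame: adult-scale stature and arm circumference
        return float(rng.normal(165.0, 10.0)), float(rng.normal(26.0, 3.0))
    # near-zero: device-failure junk readings below 10 cm
    return float(rng.uniform(0.5, 10.0)), float(rng.uniform(0.5, 3.0))


def apply_scan_process(truth: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Scan sessions: bias + size-proportional error + team noise + outliers.

    Children are dropped entirely with probability ``refusal_prob`` and,
    independently, with their team's ``missingness_prob`` (failed capture or
    transmission).  Retained children contribute 1+ sessions per
    ``sessions_probs``.  The size-proportional term centres the true value on
    the cohort mean, so the configured ``scan_bias_cm`` is also the expected
    scan-minus-truth difference.
    """
    if len(truth) == 0:
        raise ValueError("truth cohort is empty")
    mean_truth = {
        "stature": float(truth["true_stature_cm"].mean()),
        "muac": float(truth["true_muac_cm"].mean()),
    }
    n_sessions_choices = np.arange(1, len(config.sessions_probs) + 1)
    rows = []
    for i, row in enumerate(truth.itertuples(index=False)):
        rng = _rng(config.seed, _SCAN, i)
        refused = rng.random() < config.refusal_prob
        lost = rng.random() < config.missingness_prob[row.team - 1]
        n_sessions = int(rng.choice(n_sessions_choices, p=config.sessions_probs))
        if refused or lost:
            continue
        scan_weight = row.true_weight_kg + config.weight_noise_sd_kg * rng.standard_normal()
        for s in range(1, n_sessions + 1):
            vals = {}
            contaminated = rng.random() < config.outlier_prob
            contam = _contaminate(rng, config.outlier_model) if contaminated else None
            for j, (m, true_val) in enumerate(
                (("stature", row.true_stature_cm), ("muac", row.true_muac_cm))
            ):
                noise = config.scan_noise_sd_cm[m][row.team - 1] * rng.standard_normal()
                v = (
                    true_val
                    + config.scan_bias_cm[m]
                    + config.scan_slope[m] * (true_val - mean_truth[m])
                    + noise
                )
                vals[m] = contam[j] if contaminated else v
            rows.append(
                (
                    row.child_id,
                    s,
                    row.team,
                    row.sex,
                    row.age_months,
                    scan_weight,
                    vals["stature"],
                    vals["muac"],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "child_id",
            "session",
            "team",
            "sex",
            "age_months",
            "weight_kg",
            "stature_cm",
            "muac_cm",
        ],
    )


def corrupt_identifiers(
    scan: pd.DataFrame, mismatch_rate: float, seed: int
) -> pd.DataFrame:
    """Pairwise-swap scan-side child IDs for ~``mismatch_rate`` of children.

    Swapped children keep their own recorded attributes (sex, age, weight) on
    the scan side — the ID now points at a different child, so the linkage
    stage sees attribute conflicts, exactly the failure mode being emulated.
    """
    if mismatch_rate == 0 or len(scan) == 0:
        return scan.copy()
    ids = np.asarray(sorted(scan["child_id"].unique()))
    if len(ids) < 2:
        raise ValueError("identifier corruption needs at least 2 children")
    rng = _rng(seed, _SWAP)
    n_pairs = int(round(mismatch_rate * len(ids) / 2.0))
    n_pairs = min(n_pairs, len(ids) // 2)
    chosen = rng.choice(ids, size=2 * n_pairs, replace=False)
    mapping = {}
    for a, b in zip(chosen[0::2], chosen[1::2]):
        mapping[a] = b
        mapping[b] = a
    out = scan.copy()
    out["child_id"] = out["child_id"].map(lambda c: mapping.get(c, c))
    return out


def generate_differences(
    n: int,
    mean: float,
    sd: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """n iid Normal(mean, sd) paired differences (difference-level simulator)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    return mean + sd * rng.standard_normal(n)


# ---------------------------------------------------------------------------
# Assembly and I/O
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: CohortConfig, reference: GrowthReference | None = None
) -> dict[str, pd.DataFrame]:
    """Full generator: truth -> manual + scan records + roster.

    Returns {'roster', 'manual', 'scan', 'truth'}.  The roster carries the
    manual team's demographics; the scan table carries independently recorded
    demographics and has IDs corrupted at ``config.mismatch_rate``.
    """
    truth = generate_truth(config, reference)
    manual = apply_manual_process(truth, config)
    scan = apply_scan_process(truth, config)
    scan = corrupt_identifiers(scan, config.mismatch_rate, config.seed)
    roster = manual[["child_id", "team", "sex", "age_months", "weight_kg"]].copy()
    return {"roster": roster, "manual": manual, "scan": scan, "truth": truth}


_COHORT_FILES = {
    "roster": "roster.csv",
    "manual": "manual.csv",
    "scan": "scan.csv",
}


def write_cohort(tables: Mapping[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write roster/manual/scan CSVs (truth, if present, is kept out of the
    study data on purpose — the analysis must not see it)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, fname in _COHORT_FILES.items():
        path = out_dir / fname
        tables[name].to_csv(path, index=False, float_format="%.6g")
        paths[name] = path
    return paths


def load_cohort(data_dir) -> dict[str, pd.DataFrame]:
    data_dir = Path(data_dir)
    out = {}
    for name, fname in _COHORT_FILES.items():
        path = data_dir / fname
        if not path.exists():
            raise FileNotFoundError(f"cohort file missing: {path}")
        out[name] = pd.read_csv(path)
    return out
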