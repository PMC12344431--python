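"""Synthetic primary-care cohorts with known planted structure.

Emulates the data the pipeline consumes -- a dispensing-event table with free
text names and day-resolution dates, a participant covariate table, and an
optional CYP2C19 diplotype table -- together with a truth ledger recording
every planted parameter.  The generator works backwards from the exposure
definition: each participant's intended DDI status is drawn from a logistic
model with planted log-odds-ratios (intercept solved numerically to hit the
target marginal prevalence, 46.8% by default), and prescription dates are then
constructed so the 98-day window rule and ±14-day padding classify the
participant exactly as intended.  Participants intended non-DDI may still
receive interacting drugs, but only in windows ending at least 29 days before
their first citalopram prescription, so padded intervals can never meet --
"no DDI" is a non-trivial outcome that exercises the boundary logic.

Known planted effects (defaults, as log odds ratios): treatment-resistant
depression ln 2.12, suicidality ln 2.21, heart attack ln 1.91, anxiety
ln 1.53, depression ln 1.46; every other covariate 0.  A configurable
fraction of DDI participants (default 0.24) receives only single-prescription
interacting windows, exercising the duration-exclusion path.  Drug names are
emitted with case jitter, trade-name substitution and dose/formulation
suffixes so annotation is exercised on realistic text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

EPOCH = np.datetime64("1990-01-01")

DEFAULT_PLANTED_LOG_OR: dict[str, float] = {
    "trd": math.log(2.12),
    "suicidality": math.log(2.21),
    "heart_attack": math.log(1.91),
    "anxiety": math.log(1.53),
    "depression": math.log(1.46),
}

DEFAULT_COMORBIDITY_PREVALENCE: dict[str, float] = {
    "depression": 0.60,
    "anxiety": 0.30,
    "trd": 0.15,
    "suicidality": 0.02,
    "heart_attack": 0.03,
    "diabetes": 0.07,
    "hypertension": 0.25,
    "cancer": 0.08,
    "stroke": 0.02,
    "angina": 0.03,
}

DEFAULT_ALLELE_FREQS: dict[str, float] = {"*1": 0.63, "*2": 0.20, "*17": 0.15,
                                          "*3": 0.02}

# canonical name -> (sampling weight, trade-name variants used in free text)
DRUG_POOL: dict[str, tuple[float, tuple[str, ...]]] = {
    "omeprazole": (0.30, ("omeprazole", "prilosec", "losec")),
    "lansoprazole": (0.25, ("lansoprazole", "prevacid", "zoton")),
    "diazepam": (0.15, ("diazepam", "valium")),
    "amitriptyline": (0.12, ("amitriptyline", "elavil")),
    "quinidine": (0.05, ("quinidine", "quinora")),
    "hydroxyzine": (0.05, ("hydroxyzine", "atarax")),
    "ketoconazole": (0.08, ("ketoconazole", "nizoral")),
}

NOISE_DRUGS = ("paracetamol", "simvastatin", "aspirin", "co-amilofruse")
DOSE_SUFFIXES = ("", " 10mg tablets", " 20mg capsules", " 40mg tablets",
                 " oral solution", " orodispersible")

_NAME_VARIANTS: dict[str, tuple[str, ...]] = {
    "citalopram": ("citalopram", "cipramil", "celexa"),
    **{drug: variants for drug, (_, variants) in DRUG_POOL.items()},
    **{drug: (drug,) for drug in NOISE_DRUGS},
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""
    n_participants: int = 20_000
    seed: int = 0
    target_prevalence: float = 0.468
    planted_log_or: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_LOG_OR))
    # covariate marginals
    female_frac: float = 0.67
    age_mean: float = 54.0
    age_sd: float = 8.0
    townsend_mean: float = -1.5
    townsend_sd: float = 3.0
    bmi_mean: float = 27.5
    bmi_sd: float = 5.0
    white_frac: float = 0.95
    ever_smoked_frac: float = 0.45
    qualification_probs: Mapping[str, float] = field(default_factory=lambda: {
        "degree": 0.33, "a_levels": 0.11, "o_levels": 0.22, "none": 0.34})
    comorbidity_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE))
    missing_frac: Mapping[str, float] = field(default_factory=lambda: {
        "bmi": 0.02, "townsend": 0.01, "qualifications": 0.03})
    # prescription process
    mean_extra_cital_windows: float = 0.45   # windows per participant = 1 + Binom(2, p/2)
    mean_extra_cital_rx: float = 5.0         # rx per window = 1 + Poisson(mean)
    repeat_gap_lo: int = 21                  # within-window inter-rx gap (days)
    repeat_gap_hi: int = 84
    discontinuation_gap_lo: int = 120        # between-window gap, > 98 by construction
    discontinuation_gap_hi: int = 400
    mean_extra_interacting_drugs: float = 0.96   # distinct drugs = 1 + Poisson(mean)
    second_window_prob: float = 0.35         # chance of a 2nd overlapping window per drug
    single_rx_only_frac: float = 0.24        # DDI participants with single-rx windows only
    nonddi_interacting_frac: float = 0.35    # non-DDI participants given clear-of-overlap drugs
    overlap_median_days: float = 68.0        # lognormal target overlap duration
    overlap_log_sd: float = 1.1
    noise_drug_prob: float = 0.3
    # genetics
    allele_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ALLELE_FREQS))
    diplotype_coverage: float = 0.90
    unknown_allele_frac: float = 0.005
    phenotype_duration_shift: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie strictly in (0, 1)")
        if abs(sum(self.allele_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        for name in self.planted_log_or:
            if name not in self.comorbidity_prevalence:
                raise ValueError(f"planted effect on unknown covariate {name!r}")


@dataclass
class SyntheticCohort:
    """Generator output: pipeline inputs plus the truth ledger."""
    events: pd.DataFrame          # participant_id, drug_name, date
    covariates: pd.DataFrame
    diplotypes: pd.DataFrame      # participant_id, allele1, allele2
    truth: dict


# ---------------------------------------------------------------------------
# Covariates and intended status
# ---------------------------------------------------------------------------

def _draw_covariates(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_participants
    quals = list(cfg.qualification_probs)
    cov = pd.DataFrame({
        "participant_id": [f"P{i:06d}" for i in range(n)],
        "sex": np.where(rng.random(n) < cfg.female_frac, "female", "male"),
        "townsend": rng.normal(cfg.townsend_mean, cfg.townsend_sd, n),
        "qualifications": rng.choice(quals, size=n,
                                     p=list(cfg.qualification_probs.values())),
        "bmi": rng.normal(cfg.bmi_mean, cfg.bmi_sd, n),
        "ethnicity": np.where(rng.random(n) < cfg.white_frac, "white", "other"),
        "ever_smoked": (rng.random(n) < cfg.ever_smoked_frac).astype(int),
    })
    for name, prev in cfg.comorbidity_prevalence.items():
        cov[name] = (rng.random(n) < prev).astype(int)
    return cov


def _linear_predictor(cov: pd.DataFrame, planted: Mapping[str, float]) -> np.ndarray:
    lp = np.zeros(len(cov))
    for name, beta in planted.items():
        if beta:
            lp += beta * cov[name].to_numpy(dtype=float)
    return lp


def solve_intercept(config: GeneratorConfig,
                    linear_predictor: np.ndarray | None = None) -> float:
    """Intercept b0 with E[expit(b0 + X beta)] equal to the target prevalence.

    Solved by root-finding over a Monte-Carlo draw of the covariate
    distribution (or the realised one, when supplied), to within 1e-3 on the
    prevalence scale.
    """
    if linear_predictor is None:
        rng = np.random.default_rng(config.seed + 777)
        mc = _draw_covariates(
            GeneratorConfig(**{**config.__dict__, "n_participants": 100_000}), rng)
        linear_predictor = _linear_predictor(mc, config.planted_log_or)
    lp = np.asarray(linear_predictor, dtype=float)

    def gap(b0: float) -> float:
        return float(expit(b0 + lp).mean() - config.target_prevalence)

    lo, hi = -25.0, 25.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("no intercept can reach the target prevalence")
    return float(brentq(gap, lo, hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# Prescription-event construction
# ---------------------------------------------------------------------------

def _noisy_names(canonical: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised free-text rendering: trade-name substitution, case jitter,
    dose/formulation suffixes."""
    names = np.empty(len(canonical), dtype=object)
    series = pd.Series(canonical)
    for drug, idx in series.groupby(series, sort=True).groups.items():
        variants = np.array(_NAME_VARIANTS[drug], dtype=object)
        pos = np.asarray(idx)
        names[pos] = variants[rng.integers(0, len(variants), len(pos))]
    style = rng.integers(0, 3, len(names))
    out = pd.Series(names)
    out[style == 1] = out[style == 1].str.upper()
    out[style == 2] = out[style == 2].str.capitalize()
    suffix = np.array(DOSE_SUFFIXES, dtype=object)[
        rng.integers(0, len(DOSE_SUFFIXES), len(names))]
    return (out + suffix).to_numpy()


def _window_dates(start: int, length: int, cfg: GeneratorConfig,
                  rng: np.random.Generator) -> list[int]:
    """Dates of one prescription window: day offsets spanning [start, start+length]
    with inter-prescription gaps <= repeat_gap_hi (< 98)."""
    if length <= 0:
        return [start]
    gaps = rng.integers(cfg.repeat_gap_lo, cfg.repeat_gap_hi + 1,
                        size=length // cfg.repeat_gap_lo + 1)
    offsets = np.minimum(np.concatenate(([0], np.cumsum(gaps))), length)
    return (start + np.unique(offsets)).tolist()


def _citalopram_days(cfg: GeneratorConfig, rng: np.random.Generator
                     ) -> tuple[list[int], list[tuple[int, int]]]:
    """All citalopram dispensing days for one participant, plus the
    (start, end) bounds of each intended window."""
    first = int(rng.integers(1500, 7000))
    n_windows = 1 + int(rng.binomial(2, cfg.mean_extra_cital_windows / 2))
    days: list[int] = []
    bounds: list[tuple[int, int]] = []
    pos = first
    for _ in range(n_windows):
        n_rx = 1 + int(rng.poisson(cfg.mean_extra_cital_rx))
        win = pos + np.concatenate(
            ([0], np.cumsum(rng.integers(cfg.repeat_gap_lo, cfg.repeat_gap_hi + 1,
                                         size=n_rx - 1)))).astype(int)
        days.extend(win.tolist())
        bounds.append((int(win[0]), int(win[-1])))
        pos = int(win[-1]) + int(rng.integers(cfg.discontinuation_gap_lo,
                                              cfg.discontinuation_gap_hi + 1))
    return days, bounds


def _overlapping_window(bounds: tuple[int, int], single_rx: bool,
                        duration_shift: float, cfg: GeneratorConfig,
                        rng: np.random.Generator) -> list[int]:
    """Drug dispensing days guaranteed to overlap the padded citalopram window.

    The drug window is placed inside the citalopram window's raw bounds, which
    makes the padded intersection equal to the padded drug window, so the
    realised overlap tracks the sampled target duration.
    """
    c_start, c_end = bounds
    if single_rx:
        day = int(rng.integers(c_start, c_end + 1)) if c_end > c_start else c_start
        return [day]
    target = float(rng.lognormal(math.log(cfg.overlap_median_days),
                                 cfg.overlap_log_sd)) + duration_shift
    length = max(cfg.repeat_gap_lo, int(round(target)) - 29)
    length = min(length, c_end - c_start) if c_end > c_start else 0
    if length < 1:
        # citalopram window too short to host a repeated drug window inside it;
        # fall back to a two-prescription window starting at the citalopram start
        start = c_start
        length = cfg.repeat_gap_lo
    else:
        start = int(rng.integers(c_start, c_end - length + 1))
    return _window_dates(start, length, cfg, rng)


def _clear_window(first_cital: int, cfg: GeneratorConfig,
                  rng: np.random.Generator) -> list[int]:
    """Drug dispensing days ending >= 29 days before the first citalopram
    prescription, so padded windows can never intersect."""
    end = first_cital - 29 - int(rng.integers(0, 61))
    n_rx = 1 + int(rng.poisson(1.0))
    days = [end]
    pos = end
    for _ in range(n_rx - 1):
        pos -= int(rng.integers(cfg.repeat_gap_lo, cfg.repeat_gap_hi + 1))
        days.append(pos)
    return days[::-1]


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate events, covariates and diplotypes with a truth ledger.

    Deterministic for a given config (same seed → byte-identical tables).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    if n == 0:
        empty_events = pd.DataFrame(columns=["participant_id", "drug_name", "date"])
        empty_cov = pd.DataFrame(columns=["participant_id"])
        empty_dip = pd.DataFrame(columns=["participant_id", "allele1", "allele2"])
        return SyntheticCohort(empty_events, empty_cov, empty_dip,
                               {"intended_ddi": {}, "intercept": None,
                                "planted_log_or": dict(config.planted_log_or),
                                "target_prevalence": config.target_prevalence,
                                "seed": config.seed})

    cov = _draw_covariates(config, rng)
    lp = _linear_predictor(cov, config.planted_log_or)
    intercept = solve_intercept(config, lp)
    intended = rng.random(n) < expit(intercept + lp)

    # genetics first: a planted phenotype→duration shift feeds event construction
    alleles = list(config.allele_freqs)
    freqs = list(config.allele_freqs.values())
    a1 = rng.choice(alleles, size=n, p=freqs).astype(object)
    a2 = rng.choice(alleles, size=n, p=freqs).astype(object)
    unknown = rng.random(n) < config.unknown_allele_frac
    a1 = np.where(unknown, "*99", a1)
    covered = rng.random(n) < config.diplotype_coverage
    diplotypes = pd.DataFrame({
        "participant_id": cov["participant_id"][covered],
        "allele1": a1[covered], "allele2": a2[covered],
    }).reset_index(drop=True)

    shifts = np.zeros(n)
    if config.phenotype_duration_shift:
        from .cyp2c19 import assign_phenotype, Diplotype, load_allele_table
        table = load_allele_table()
        pheno = np.array([assign_phenotype(Diplotype("x", x, y), table)
                          for x, y in zip(a1, a2)])
        pheno = np.where(covered, pheno, "indeterminate")
        for ph, shift in config.phenotype_duration_shift.items():
            shifts[pheno == ph] = shift

    drug_names = list(DRUG_POOL)
    drug_weights = np.array([DRUG_POOL[d][0] for d in drug_names])
    drug_weights = drug_weights / drug_weights.sum()

    pids: list[str] = []
    canon: list[str] = []
    days: list[int] = []
    birth_years = np.empty(n, dtype=int)
    age = rng.normal(config.age_mean, config.age_sd, n).clip(18, 90)
    single_only_flags = np.zeros(n, dtype=bool)
    # per-participant draws, batched for speed
    single_only_draw = rng.random(n) < config.single_rx_only_frac
    n_drugs_draw = 1 + rng.poisson(config.mean_extra_interacting_drugs, n)
    nonddi_draw = rng.random(n) < config.nonddi_interacting_frac
    noise_draw = rng.random(n) < config.noise_drug_prob
    noise_pick = rng.integers(0, len(NOISE_DRUGS), n)
    noise_day = rng.integers(1000, 8000, n)
    id_list = cov["participant_id"].tolist()

    def emit(pid: str, canonical: str, day_list: list[int]) -> None:
        pids.extend([pid] * len(day_list))
        canon.extend([canonical] * len(day_list))
        days.extend(day_list)

    for i in range(n):
        pid = id_list[i]
        cital_days, bounds = _citalopram_days(config, rng)
        emit(pid, "citalopram", cital_days)
        first_year = 1990 + cital_days[0] // 365
        birth_years[i] = first_year - int(round(age[i]))

        if intended[i]:
            single_only = bool(single_only_draw[i])
            single_only_flags[i] = single_only
            n_drugs = min(int(n_drugs_draw[i]), len(drug_names))
            chosen = rng.choice(len(drug_names), size=n_drugs, replace=False,
                                p=drug_weights)
            for j in chosen:
                canonical = drug_names[j]
                windows = [bounds[int(rng.integers(len(bounds)))]]
                if len(bounds) > 1 and rng.random() < config.second_window_prob:
                    other = [b for b in bounds if b != windows[0]]
                    windows.append(other[int(rng.integers(len(other)))])
                for b in windows:
                    emit(pid, canonical,
                         _overlapping_window(b, single_only, shifts[i], config, rng))
        elif nonddi_draw[i]:
            j = int(rng.choice(len(drug_names), p=drug_weights))
            emit(pid, drug_names[j], _clear_window(cital_days[0], config, rng))

        if noise_draw[i]:
            emit(pid, NOISE_DRUGS[noise_pick[i]], [int(noise_day[i])])

    cov["birth_year"] = birth_years
    for col, frac in config.missing_frac.items():
        mask = rng.random(n) < frac
        cov.loc[mask, col] = np.nan

    events = pd.DataFrame({
        "participant_id": pids,
        "drug_name": _noisy_names(np.array(canon, dtype=object), rng),
        "date": EPOCH + np.array(days, dtype="timedelta64[D]"),
    })

    truth = {
        "seed": config.seed,
        "target_prevalence": config.target_prevalence,
        "planted_log_or": dict(config.planted_log_or),
        "intercept": intercept,
        "phenotype_duration_shift": dict(config.phenotype_duration_shift),
        "intended_ddi": dict(zip(cov["participant_id"], map(bool, intended))),
        "single_rx_only": dict(zip(cov["participant_id"],
                                   map(bool, single_only_flags))),
    }
    return SyntheticCohort(events=events, covariates=cov,
                           diplotypes=diplotypes, truth=truth)
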