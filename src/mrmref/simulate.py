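"""In-silico LC-MRM-MS experiment with known ground truth.

Emulates a first-trimester serum cohort measured by targeted MRM with
stable-isotope internal standards: 83 pregnancies in randomized duplicate
across three batches, a ~139-protein panel spanning ~5.3 decades of
abundance, seven calibration levels (A-G), three surrogate-matrix QC levels,
a pooled-serum control (CLP), and blanks.

The generative model, per protein p and cohort sample s:

    conc[s, p] = median_p * 10**(sigma_p * N(0,1)) * prod_c (1 + beta_{p,c} * z_{s,c})

with ``z`` the mean-centered covariate, so an ordinary linear model of the
MoM value on covariates is correctly specified. Measured response ratios add
multiplicative structure on top of the true concentration:

    ratio = conc / sis_conc * 10**(batch_shift[b, p] + sample_shift[s]) * e

where ``e`` is log-normal technical noise with a target CV. Batch and sample
shifts apply only to serum-matrix material (cohort samples and the pooled
serum control) — they model matrix/digestion effects that the surrogate-matrix
calibrators and QCs do not share, which is why they survive calibration and
must be removed by normalization. Ground truth (true concentrations, shifts,
effect sizes) is returned alongside, so every downstream stage has a
parameter-recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_LEVELS
from .io_formats import (
    PEAK_COLUMNS,
    Panel,
    PanelEntry,
    validate_annotations,
    validate_peak_table,
)

# Cohort covariate distributions (medians and observed ranges of a healthy
# first-trimester screening population).
AGE_MEDIAN, AGE_SD, AGE_RANGE = 30.5, 4.0, (20.5, 37.3)
BMI_MEDIAN, BMI_SD, BMI_RANGE = 21.2, 2.8, (15.6, 30.1)
GA_RANGE = (11.3, 13.9)
PARITY_PROBS = (0.48, 0.39, 0.12, 0.01)
MYOMA_P = 0.10
MALE_P = 0.49

#: q95/q5 fold-change corresponds to 2 * z_{0.95} = 3.2897 log-sd units.
_Z90 = 2.0 * stats.norm.ppf(0.95)


def _default_covariate_effects() -> tuple[tuple[str, str, float], ...]:
    """Designed protein-covariate effects (beta per unit centered covariate,
    on the MoM scale). Magnitudes chosen so effects are detectable but
    moderate at n = 83, echoing the dominant real-cohort associations
    (BMI and parity affecting the most proteins, then fetal sex)."""
    return (
        ("PROT010", "bmi", 0.030),
        ("PROT011", "bmi", -0.030),
        ("PROT012", "bmi", 0.040),
        ("PROT013", "parity", 0.100),
        ("PROT014", "parity", -0.100),
        ("PROT015", "fetal_sex_male", 0.120),
        ("PROT016", "fetal_sex_male", -0.120),
        ("PROT017", "age", -0.015),
        ("PROT018", "ga_collection", 0.100),
        ("PROT019", "ga_collection", -0.100),
        ("PROT020", "myoma", -0.150),
        ("PROT021", "parity", 0.120),
    )


def _default_dropout() -> tuple[tuple[str, float], ...]:
    """24 panel proteins engineered to sit below the LLOQ in 75% of cohort
    samples — the 'targeted but not reliably detected' fraction."""
    return tuple((f"PROT{i:03d}", 0.75) for i in range(116, 140))


def _default_noisy() -> tuple[tuple[str, float], ...]:
    """Two proteins with inflated matrix CV (acute-phase-like analytes whose
    serum measurements vary far beyond the 20% exclusion threshold while
    their pure-peptide calibration standards stay clean)."""
    return (("PROT003", 1.0), ("PROT004", 1.0))


@dataclass
class SimConfig:
    """Parameters of the simulated experiment (defaults are the study
    conditions: 83 samples, 3 batches, 139-protein panel over 5.3 decades,
    ~8% technical CV on serum-matrix material, 0.05 log10 batch and sample
    shifts).

    ``tech_cv`` is the replicate CV of serum/BSA-matrix measurements
    (cohort samples, QCA-C, CLP); calibration standards — chemically
    defined peptide spikes in clean surrogate matrix — use the lower
    ``standard_cv`` (default half of ``tech_cv``). ``noisy_proteins``
    overrides the matrix CV for unstable analytes without touching their
    calibration."""

    n_samples: int = 83
    n_batches: int = 3
    n_proteins: int = 139
    seed: int = 0
    abundance_range_log10: float = 5.3
    log10_median_min: float = 0.4
    frac_high_variance: float = 0.10
    batch_shift_sd: float = 0.05
    sample_shift_sd: float = 0.05
    tech_cv: float = 0.08
    standard_cv: float | None = None  # None -> tech_cv / 2
    bio_sigma_low: tuple[float, float] = (0.03, 0.13)
    high_variance_folds: tuple[float, float] = (3.5, 9.0)
    covariate_effects: tuple[tuple[str, str, float], ...] = field(
        default_factory=_default_covariate_effects
    )
    dropout: tuple[tuple[str, float], ...] = field(default_factory=_default_dropout)
    noisy_proteins: tuple[tuple[str, float], ...] = field(
        default_factory=_default_noisy
    )
    sis_conc: float = 100.0
    cal_span: float = 20.0
    n_standard_replicates: int = 2
    n_qc_replicates: int = 3
    n_blank_replicates: int = 2
    level_labels: tuple[str, ...] = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        for name, val in (
            ("frac_high_variance", self.frac_high_variance),
            ("tech_cv", self.tech_cv),
        ):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        for _, frac in self.dropout:
            if not 0 <= frac <= 1:
                raise ValueError("dropout fractions must be in [0, 1]")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")

    @property
    def resolved_standard_cv(self) -> float:
        return self.tech_cv / 2.0 if self.standard_cv is None else self.standard_cv

    def protein_names(self) -> list[str]:
        names = ["PZP_like", "LPA_like"]
        names += [f"PROT{i:03d}" for i in range(3, self.n_proteins + 1)]
        return names[: self.n_proteins]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_conc: pd.DataFrame  # samples x proteins, fmol/uL
    sample_effects: pd.Series  # per-sample log10 shift
    sample_batches: pd.Series  # per-sample batch assignment
    batch_effects: pd.DataFrame  # batches x proteins log10 shifts
    true_betas: tuple[tuple[str, str, float], ...]
    protein_params: pd.DataFrame  # median, sigma_log10, tech_cv per protein
    clp_profile: pd.Series  # pooled-serum control nominal profile

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.true_conc.to_csv(outdir / "true_conc.csv", index_label="sample_id")
        self.sample_effects.rename("log10_shift").to_csv(
            outdir / "sample_effects.csv", index_label="sample_id"
        )
        self.batch_effects.to_csv(outdir / "batch_effects.csv", index_label="batch")
        self.protein_params.to_csv(
            outdir / "protein_params.csv", index_label="protein_id"
        )
        self.clp_profile.rename("conc").to_csv(
            outdir / "clp_profile.csv", index_label="protein_id"
        )
        with open(outdir / "true_betas.json", "w") as fh:
            json.dump([list(b) for b in self.true_betas], fh, indent=1)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _truncated_normal(
    rng: np.random.Generator, loc: float, scale: float, bounds: tuple[float, float], n: int
) -> np.ndarray:
    a, b = (bounds[0] - loc) / scale, (bounds[1] - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw the annotated cohort (age, BMI, GA, parity, myoma, fetal sex,
    batch assignment). Deterministic under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    age = _truncated_normal(rng, AGE_MEDIAN, AGE_SD, AGE_RANGE, n)
    bmi = _truncated_normal(rng, BMI_MEDIAN, BMI_SD, BMI_RANGE, n)
    ga = rng.uniform(*GA_RANGE, size=n)
    parity = rng.choice([1, 2, 3, 4], size=n, p=PARITY_PROBS)
    myoma = rng.binomial(1, MYOMA_P, size=n)
    male = rng.binomial(1, MALE_P, size=n)
    batches = np.array(
        [f"B{(i % config.n_batches) + 1}" for i in range(n)] if config.n_batches else []
    )
    rng.shuffle(batches)
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": np.round(age, 2),
            "bmi": np.round(bmi, 2),
            "ga_collection": np.round(ga, 2),
            "parity": parity,
            "myoma": myoma,
            "fetal_sex_male": male,
            "batch": batches,
        }
    )
    if n == 0:
        return df.set_index("sample_id")
    return validate_annotations(df, ga_window=(GA_RANGE[0] - 0.5, GA_RANGE[1] + 0.5))


# ---------------------------------------------------------------------------
# true concentrations
# ---------------------------------------------------------------------------


def _protein_params(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    names = config.protein_names()
    p = config.n_proteins
    medians = 10.0 ** rng.uniform(
        config.log10_median_min,
        config.log10_median_min + config.abundance_range_log10,
        size=p,
    )
    lo, hi = config.bio_sigma_low
    sigma = rng.uniform(lo, hi, size=p)
    n_high = int(round(config.frac_high_variance * p))
    if n_high >= 1 and p >= 1:
        # the two designated extreme proteins: ~124-fold and ~9.9-fold spreads
        sigma[0] = np.log10(123.9) / _Z90
    if n_high >= 2 and p >= 2:
        sigma[1] = np.log10(9.9) / _Z90
    if n_high > 2:
        folds = rng.uniform(*config.high_variance_folds, size=n_high - 2)
        sigma[2:n_high] = np.log10(folds) / _Z90
    tech = np.full(p, config.tech_cv)
    noisy = dict(config.noisy_proteins)
    params = pd.DataFrame(
        {"median": medians, "sigma_log10": sigma, "tech_cv": tech}, index=names
    )
    for name, cv in noisy.items():
        if name in params.index:
            params.loc[name, "tech_cv"] = cv
    params.index.name = "protein_id"
    return params


def centered_covariates(annotations: pd.DataFrame) -> pd.DataFrame:
    cols = ["age", "bmi", "ga_collection", "parity", "myoma", "fetal_sex_male"]
    z = annotations[cols].astype(float)
    return z - z.mean()


def simulate_true_concentrations(
    config: SimConfig, annotations: pd.DataFrame
) -> GroundTruth:
    """Draw true concentrations plus the technical effects that the plate
    simulation will superimpose. Covariate effects are multiplicative,
    ``(1 + beta * z)`` with z mean-centered, so a linear MoM model is
    correctly specified."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    params = _protein_params(config, rng)
    names = params.index.tolist()
    n, p = len(annotations), config.n_proteins

    base = params["median"].to_numpy() * 10.0 ** (
        params["sigma_log10"].to_numpy()[None, :] * rng.standard_normal((n, p))
    )
    z = centered_covariates(annotations)
    effect = np.ones((n, p))
    for prot, cov, beta in config.covariate_effects:
        if prot not in names:
            continue
        j = names.index(prot)
        mult = 1.0 + beta * z[cov].to_numpy()
        if (mult <= 0).any():
            raise ValueError(
                f"covariate effect ({prot}, {cov}, beta={beta}) drives "
                "(1 + beta*z) non-positive for some sample"
            )
        effect[:, j] *= mult
    true_conc = pd.DataFrame(base * effect, index=annotations.index, columns=names)

    sample_effects = pd.Series(
        rng.normal(0.0, config.sample_shift_sd, size=n),
        index=annotations.index,
        name="log10_shift",
    )
    batch_ids = sorted(annotations["batch"].unique()) if n else [
        f"B{i + 1}" for i in range(config.n_batches)
    ]
    batch_effects = pd.DataFrame(
        rng.normal(0.0, config.batch_shift_sd, size=(len(batch_ids), p)),
        index=pd.Index(batch_ids, name="batch"),
        columns=names,
    )
    clp_profile = true_conc.mean(axis=0) if n else params["median"].copy()
    clp_profile.name = "conc"
    return GroundTruth(
        true_conc=true_conc,
        sample_batches=annotations["batch"].copy(),
        sample_effects=sample_effects,
        batch_effects=batch_effects,
        true_betas=tuple(config.covariate_effects),
        protein_params=params,
        clp_profile=clp_profile,
    )


# ---------------------------------------------------------------------------
# panel design
# ---------------------------------------------------------------------------


def design_panel(config: SimConfig, ground_truth: GroundTruth) -> Panel:
    """Build the assay panel around each protein's design median: levels A-G
    geometric from median/cal_span to median*cal_span, QCs at low/mid/high
    points of that range. Dropout proteins get their LLOQ raised to the
    configured below-LLOQ quantile of the *measured* cohort distribution
    (biological spread plus batch/sample shifts plus duplicate-averaged
    technical noise), so the designed clamping fraction survives the
    measurement process."""
    dropout = dict(config.dropout)
    levels = config.level_labels
    k = len(levels)
    entries = []
    for name, row in ground_truth.protein_params.iterrows():
        median, sigma = row["median"], row["sigma_log10"]
        lloq = median / config.cal_span
        if name in dropout:
            frac = dropout[name]
            tech_log10 = np.sqrt(np.log1p(row["tech_cv"] ** 2)) / np.log(10)
            total_sd = np.sqrt(
                sigma**2
                + config.batch_shift_sd**2
                + config.sample_shift_sd**2
                + tech_log10**2 / 2.0  # duplicates averaged
            )
            lloq = median * 10.0 ** (total_sd * stats.norm.ppf(frac))
        hloq = lloq * config.cal_span**2
        concs = np.geomspace(lloq, hloq, k)
        entries.append(
            PanelEntry(
                protein_id=name,
                peptide_id=f"{name}_pep",
                level_concs={lv: float(c) for lv, c in zip(levels, concs)},
                sis_conc=config.sis_conc,
                qc_concs={
                    "QCA": float(concs[0] * 3.0),
                    "QCB": float(np.sqrt(concs[0] * concs[-1])),
                    "QCC": float(concs[-1] / 3.0),
                },
            )
        )
    return Panel(entries)


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------


def _lognormal_noise(
    rng: np.random.Generator, cv: np.ndarray | float, shape: tuple[int, ...]
) -> np.ndarray:
    """Multiplicative noise with median 1 and SD/mean equal to ``cv``."""
    sigma = np.sqrt(np.log1p(np.asarray(cv, dtype=float) ** 2))
    return np.exp(sigma * rng.standard_normal(shape))


def simulate_plates(
    config: SimConfig, ground_truth: GroundTruth, panel: Panel
) -> pd.DataFrame:
    """Emit the long-format peak table: cohort duplicates, per-batch
    calibration standards, surrogate-matrix QCs, pooled-serum controls, and
    blanks. Serum-matrix rows (cohort, CLP) carry the batch and sample
    log-shifts; surrogate-matrix rows carry technical noise only."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    gt = ground_truth
    names = gt.protein_params.index.tolist()
    tech_cv = gt.protein_params["tech_cv"].to_numpy()  # serum/BSA matrix CV
    std_cv = config.resolved_standard_cv
    sis = np.array([panel[f"{n}_pep"].sis_conc for n in names])
    peptides = [f"{n}_pep" for n in names]
    batch_ids = list(gt.batch_effects.index)
    rows: list[pd.DataFrame] = []

    def emit(sample_id, role, batch, replicate, ratios):
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "role": role,
                    "batch": batch,
                    "replicate": replicate,
                    "peptide": peptides,
                    "ratio": ratios,
                }
            )
        )

    # cohort samples, in duplicate, within the sample's assigned batch
    for sid in gt.true_conc.index:
        batch = gt.sample_batches.loc[sid]
        shift = 10.0 ** (
            gt.batch_effects.loc[batch].to_numpy() + gt.sample_effects.loc[sid]
        )
        base = gt.true_conc.loc[sid].to_numpy() / sis * shift
        for rep in (1, 2):
            emit(sid, "cohort", batch, rep, base * _lognormal_noise(rng, tech_cv, base.shape))

    levels = panel.levels
    nominal = {
        lv: np.array([panel[pep].level_concs[lv] for pep in peptides]) for lv in levels
    }
    qc_nominal = {
        qc: np.array([panel[pep].qc_concs[qc] for pep in peptides])
        for qc in ("QCA", "QCB", "QCC")
    }
    clp = gt.clp_profile.reindex(names).to_numpy()
    lloq = nominal[levels[0]]

    for batch in batch_ids:
        bshift = 10.0 ** gt.batch_effects.loc[batch].to_numpy()
        # calibration standards: clean peptide spikes, low replicate noise
        for lv in levels:
            base = nominal[lv] / sis
            for rep in range(1, config.n_standard_replicates + 1):
                emit(
                    f"{batch}_std{lv}_r{rep}",
                    f"standard:{lv}",
                    batch,
                    rep,
                    base * _lognormal_noise(rng, std_cv, base.shape),
                )
        # surrogate-matrix QCs
        for qc in ("QCA", "QCB", "QCC"):
            base = qc_nominal[qc] / sis
            for rep in range(1, config.n_qc_replicates + 1):
                emit(
                    f"{batch}_{qc}_r{rep}",
                    f"qc:{qc}",
                    batch,
                    rep,
                    base * _lognormal_noise(rng, tech_cv, base.shape),
                )
        # pooled-serum control: serum matrix, so batch shift plus its own
        # per-preparation sample shift
        for rep in range(1, config.n_qc_replicates + 1):
            prep_shift = 10.0 ** rng.normal(0.0, config.sample_shift_sd)
            base = clp / sis * bshift * prep_shift
            emit(
                f"{batch}_CLP_r{rep}",
                "qc:CLP",
                batch,
                rep,
                base * _lognormal_noise(rng, tech_cv, base.shape),
            )
        # process blanks: trace background well below the LLOQ
        for rep in range(1, config.n_blank_replicates + 1):
            base = 0.02 * lloq / sis
            emit(
                f"{batch}_blank_r{rep}",
                "blank",
                batch,
                rep,
                base * _lognormal_noise(rng, tech_cv, base.shape),
            )

    table = pd.concat(rows, ignore_index=True)[PEAK_COLUMNS]
    return validate_peak_table(table, levels)


# ---------------------------------------------------------------------------
# one-call experiment
# ---------------------------------------------------------------------------


@dataclass
class Experiment:
    """A complete simulated experiment bundle."""

    config: SimConfig
    annotations: pd.DataFrame
    ground_truth: GroundTruth
    panel: Panel
    peak_table: pd.DataFrame


def simulate_experiment(config: SimConfig | None = None, **kwargs) -> Experiment:
    """Convenience wrapper running cohort -> truth -> panel -> plates."""
    if config is None:
        config = SimConfig(**kwargs)
    annotations = simulate_cohort(config)
    gt = simulate_true_concentrations(config, annotations)
    panel = design_panel(config, gt)
    peaks = simulate_plates(config, gt, panel)
    return Experiment(config, annotations, gt, panel, peaks)

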