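"""Synthetic neonatal cohorts with the statistical structure the analysis assumes.

The generator emulates, at the level of sufficient statistics, a
resting-state fMRI cohort of term and preterm neonates:

* birth ages drawn from truncated normals matching the study cohort
  (preterm mean 31.96 wk, term mean 40.07 wk), scan ages tied to birth
  age and to a term-equivalent window, with a subset of preterm
  subjects scanned twice (once shortly after birth, once at
  term-equivalent age);
* a single maturation scalar mu in (0, 1) per scan, increasing with
  postmenstrual age at scan under a linear or logarithmic law, with an
  optional deficit proportional to weeks born before term;
* a modular (block-constant) 90-region correlation matrix whose
  within-module correlation equals mu and whose between-module
  correlation is mu minus a fixed gap — the simplest structure under
  which strength, clustering and efficiency all rise, and path length
  falls, as mu rises;
* multivariate-normal region time series from that matrix plus white
  observation noise, and a log-normal DVARS-like motion score.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import add_group_column
from .connectome import AAL90_LABELS

logger = logging.getLogger(__name__)

#: birth-age distribution targets (weeks): mean and SD of the truncated normals
PRETERM_GA_MEAN, PRETERM_GA_SD = 31.96, 3.92
TERM_GA_MEAN, TERM_GA_SD = 40.07, 1.40
PRETERM_GA_RANGE = (23.0, 37.0)
TERM_GA_RANGE = (37.0, 42.5)
PMA_RANGE = (23.0, 44.0)

MATURATION_FORMS = ("linear", "logarithmic", "quadratic")

#: offset subtracted from PMA inside the maturation law so the log
#: argument stays positive over the scan window 23-44 wk
AGE_OFFSET = 20.0


@dataclass(frozen=True)
class MaturationLaw:
    """Ground-truth maturation scalar mu(ga_birth, pma_scan) in (0, 1).

    ``params`` are (intercept, slope) for the linear and logarithmic
    forms, or (intercept, slope, curvature) for the quadratic form, all
    applied to x = pma_scan - 20 (ln x for the logarithmic form).
    ``birth_penalty`` subtracts penalty * max(0, 37 - ga_birth), the
    maturational deficit per week of prematurity.  Output is clipped to
    (0.01, 0.99).
    """

    form: str = "logarithmic"
    params: tuple[float, ...] = (-0.10, 0.22)
    birth_penalty: float = 0.006

    def __post_init__(self) -> None:
        if self.form not in MATURATION_FORMS:
            raise ValueError(f"form must be one of {MATURATION_FORMS}")
        need = 3 if self.form == "quadratic" else 2
        if len(self.params) != need:
            raise ValueError(f"{self.form} form needs {need} params, got {len(self.params)}")

    def __call__(self, ga_birth, pma_scan):
        ga = np.asarray(ga_birth, float)
        pma = np.asarray(pma_scan, float)
        x = pma - AGE_OFFSET
        if self.form == "logarithmic":
            if np.any(x <= 0):
                raise ValueError(
                    f"pma_scan must exceed {AGE_OFFSET} weeks for the logarithmic form"
                )
            mu = self.params[0] + self.params[1] * np.log(x)
        elif self.form == "linear":
            mu = self.params[0] + self.params[1] * x
        else:
            a, b, c = self.params
            mu = a + b * x + c * x * x
        mu = mu - self.birth_penalty * np.maximum(0.0, 37.0 - ga)
        out = np.clip(mu, 0.01, 0.99)
        return float(out) if out.ndim == 0 else out


def maturation_level(ga_birth, pma_scan, law: MaturationLaw):
    """Evaluate a maturation law (see :class:`MaturationLaw`)."""
    return law(ga_birth, pma_scan)


#: ground-truth laws for trajectory-recovery simulations, one per model form.
#: The birth-age penalty is zero here: it is a between-subject device for the
#: cross-sectional generator, and a subject-level offset correlated with scan
#: age would sit outside the random-intercept family the models assume.
DEFAULT_TRAJECTORY_LAWS = {
    "linear": MaturationLaw("linear", (0.25, 0.018), birth_penalty=0.0),
    "quadratic": MaturationLaw("quadratic", (0.15, 0.042, -0.0008), birth_penalty=0.0),
    "logarithmic": MaturationLaw("logarithmic", (-0.10, 0.22), birth_penalty=0.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to generate one cohort.

    Cohort sizes default to the study composition (332 term, 115
    preterm scans, 26 preterm subjects scanned twice); tests use smaller
    cohorts and shorter series.  ``sex_effect`` is added to mu for male
    scans.  ``noise_sd`` is the white observation-noise SD relative to
    the unit-variance network signal; it attenuates all empirical
    correlations by 1/(1 + noise_sd^2) without changing their ordering.
    """

    n_term: int = 332
    n_preterm: int = 115
    n_longitudinal: int = 26
    n_regions: int = 90
    n_modules: int = 6
    timepoints: int = 2300
    maturation: MaturationLaw = field(default_factory=MaturationLaw)
    within_between_gap: float = 0.25
    noise_sd: float = 0.3
    sex_effect: float = 0.01
    dvars_log_mean: float = 0.18   # ln-scale mean of the log-normal DVARS score
    dvars_log_sd: float = 0.25
    abnormal_score_rate: float = 0.0  # fraction of scans given radiology score 3-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_longitudinal > self.n_preterm:
            raise ValueError(
                f"n_longitudinal={self.n_longitudinal} exceeds n_preterm={self.n_preterm}"
            )
        if min(self.n_term, self.n_preterm) < 0 or self.n_regions < 2:
            raise ValueError("counts must be nonnegative and n_regions >= 2")
        if self.within_between_gap <= 0:
            raise ValueError("within_between_gap must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a cohort metadata table (one row per scan session).

    Preterm subjects not in the longitudinal subset and all term
    subjects get one scan; the first ``n_longitudinal`` preterm subjects
    get two sessions, the first shortly after birth (PMA < 37) and the
    second at term-equivalent age (PMA in [37, 44]).  Sexes are balanced
    to within one subject within each arm.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    rows: list[dict] = []

    ga_pre = _truncnorm(rng, PRETERM_GA_MEAN, PRETERM_GA_SD, *PRETERM_GA_RANGE,
                        config.n_preterm)
    ga_term = _truncnorm(rng, TERM_GA_MEAN, TERM_GA_SD, *TERM_GA_RANGE, config.n_term)

    def sexes(n):
        half = np.array(["male", "female"] * (n // 2 + 1))[:n]
        return rng.permutation(half)

    sex_pre, sex_term = sexes(config.n_preterm), sexes(config.n_term)

    def dvars(n):
        return np.exp(rng.normal(config.dvars_log_mean, config.dvars_log_sd, n))

    def scores(n):
        s = rng.choice([1, 2], size=n, p=[0.55, 0.45])
        if config.abnormal_score_rate > 0:
            bad = rng.random(n) < config.abnormal_score_rate
            s[bad] = rng.choice([3, 4, 5], size=int(bad.sum()))
        return s

    # preterm subjects
    dv = dvars(config.n_preterm * 2)
    sc = scores(config.n_preterm * 2)
    for k in range(config.n_preterm):
        ga = float(ga_pre[k])
        sid = f"sub-P{k + 1:04d}"
        longitudinal = k < config.n_longitudinal
        if longitudinal:
            pma1 = min(ga + rng.gamma(2.0, 0.75), 36.9)
            rows.append(dict(subject_id=sid, session_id=f"{sid}_ses-1", ga_birth=ga,
                             pma_scan=max(pma1, ga), sex=sex_pre[k],
                             mean_dvars=float(dv[2 * k]), radiology_score=int(sc[2 * k])))
        pma2 = float(_truncnorm(rng, 41.2, 1.6, max(37.0, ga + 0.1), 44.0, 1)[0])
        rows.append(dict(subject_id=sid,
                         session_id=f"{sid}_ses-2" if longitudinal else f"{sid}_ses-1",
                         ga_birth=ga, pma_scan=pma2, sex=sex_pre[k],
                         mean_dvars=float(dv[2 * k + 1]), radiology_score=int(sc[2 * k + 1])))

    # term subjects: scanned a short interval after birth
    dv = dvars(config.n_term)
    sc = scores(config.n_term)
    for k in range(config.n_term):
        ga = float(ga_term[k])
        pma = min(ga + rng.gamma(2.0, 0.75), PMA_RANGE[1])
        sid = f"sub-T{k + 1:04d}"
        rows.append(dict(subject_id=sid, session_id=f"{sid}_ses-1", ga_birth=ga,
                         pma_scan=pma, sex=sex_term[k], mean_dvars=float(dv[k]),
                         radiology_score=int(sc[k])))

    frame = pd.DataFrame(rows)
    frame["pma_scan"] = frame["pma_scan"].clip(*PMA_RANGE)
    return add_group_column(frame)


def ground_truth_covariance(mu: float, config: GeneratorConfig) -> np.ndarray:
    """Block-constant correlation matrix driven by one maturation scalar.

    Within-module correlation is mu; between-module correlation is
    max(0, mu - gap); the diagonal is 1.  A small ridge is blended in if
    needed to restore positive-definiteness.
    """
    if not (0 < mu < 1):
        raise ValueError(f"mu must be in (0, 1), got {mu}")
    r = config.n_regions
    modules = module_assignment(r, config.n_modules)
    r_b = max(0.0, mu - config.within_between_gap)
    same = modules[:, None] == modules[None, :]
    cov = np.where(same, mu, r_b)
    np.fill_diagonal(cov, 1.0)
    for ridge in (0.0, 1e-8, 1e-6, 1e-4, 1e-2):
        cand = (cov + ridge * np.eye(r)) / (1 + ridge)
        if np.linalg.eigvalsh(cand)[0] > 1e-10:
            return cand
    raise ValueError("could not reach a positive-definite covariance")


def module_assignment(n_regions: int, n_modules: int) -> np.ndarray:
    """Contiguous module labels; any remainder goes to the last module."""
    size = n_regions // n_modules
    labels = np.repeat(np.arange(n_modules), size)
    return np.concatenate([labels, np.full(n_regions - len(labels), n_modules - 1)])


def simulate_timeseries(
    cov: np.ndarray,
    timepoints: int,
    rng: np.random.Generator | int,
    noise_sd: float = 0.0,
    labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Zero-mean Gaussian series with the given covariance plus white noise."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    r = cov.shape[0]
    if timepoints < r + 2:
        import warnings

        warnings.warn(
            f"timepoints={timepoints} < n_regions+2={r + 2}: sample correlation "
            "will be rank-deficient",
            stacklevel=2,
        )
    chol = np.linalg.cholesky(cov)
    x = rng.standard_normal((timepoints, r)) @ chol.T
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal((timepoints, r))
    if labels is None:
        labels = AAL90_LABELS if r == 90 else tuple(f"ROI_{i + 1:02d}" for i in range(r))
    return pd.DataFrame(x, columns=list(labels))


def sample_balanced_cohort(
    n_per_group: int = 30,
    longitudinal_preterm: bool = False,
    seed: int = 0,
    groups: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Design-controlled cohort: equal subject counts in all seven groups.

    Birth ages are uniform within each group's GA interval.  Preterm
    subjects are scanned at term-equivalent age (optionally with an
    additional early scan when ``longitudinal_preterm``); term subjects
    are scanned a short interval after birth, as in
    :func:`sample_cohort`.  Used by calibration and directionality
    experiments where the natural group imbalance of the cohort
    distributions would starve the extreme groups.
    """
    from .cohort import GROUP_ORDER, PRETERM_GROUPS, _GROUP_EDGES

    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    edges = list(_GROUP_EDGES) + [44.0]
    wanted = GROUP_ORDER if groups is None else tuple(groups)
    rows = []
    for gi, group in enumerate(GROUP_ORDER):
        if group not in wanted:
            continue
        lo = max(edges[gi], PMA_RANGE[0])
        hi = min(edges[gi + 1], 43.0)
        ga_vals = rng.uniform(lo, hi, n_per_group)
        sexes = rng.permutation(
            np.array(["male", "female"] * (n_per_group // 2 + 1))[:n_per_group]
        )
        for k in range(n_per_group):
            ga = float(ga_vals[k])
            sid = f"sub-G{gi + 1}{k + 1:03d}"
            preterm = group in PRETERM_GROUPS
            base = dict(subject_id=sid, ga_birth=ga, sex=sexes[k],
                        radiology_score=int(rng.choice([1, 2])))
            if preterm:
                if longitudinal_preterm:
                    pma1 = max(ga, min(ga + rng.gamma(2.0, 0.75), 36.9))
                    rows.append(dict(base, session_id=f"{sid}_ses-1", pma_scan=pma1,
                                     mean_dvars=float(np.exp(rng.normal(0.18, 0.25)))))
                pma = float(_truncnorm(rng, 41.2, 1.6, max(37.0, ga + 0.1), 44.0, 1)[0])
            else:
                pma = float(min(ga + rng.gamma(2.0, 0.75), PMA_RANGE[1]))
            rows.append(dict(base, session_id=f"{sid}_ses-2" if (preterm and
                             longitudinal_preterm) else f"{sid}_ses-1",
                             pma_scan=pma,
                             mean_dvars=float(np.exp(rng.normal(0.18, 0.25)))))
    return add_group_column(pd.DataFrame(rows))


def simulate_cohort_scans(
    metadata: pd.DataFrame, config: GeneratorConfig
) -> dict[str, pd.DataFrame]:
    """One simulated time-series table per scan row of ``metadata``.

    The per-scan maturation scalar sets the ground-truth connectivity;
    male scans get ``sex_effect`` added to mu.  Per-scan random streams
    are spawned from the config seed keyed by row order, so the result
    is reproducible and insensitive to dict iteration order.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(metadata) + 1)
    series: dict[str, pd.DataFrame] = {}
    for k, row in enumerate(metadata.itertuples(index=False)):
        mu = config.maturation(row.ga_birth, row.pma_scan)
        if row.sex == "male":
            mu = float(np.clip(mu + config.sex_effect, 0.01, 0.99))
        cov = ground_truth_covariance(mu, config)
        rng = np.random.default_rng(children[k + 1])
        series[row.session_id] = simulate_timeseries(
            cov, config.timepoints, rng, noise_sd=config.noise_sd
        )
    return series


def generate_cohort_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Metadata plus one simulated time-series table per scan session."""
    metadata = sample_cohort(config)
    return metadata, simulate_cohort_scans(metadata, config)


def write_cohort_dataset(config: GeneratorConfig, outdir) -> pd.DataFrame:
    """Generate a cohort and write it to disk in the plain-text layout.

    Produces ``metadata.tsv``, a ``timeseries/`` directory with one TSV
    per scan and a ``manifest.tsv`` mapping session_id to file.  Returns
    the metadata table.
    """
    from pathlib import Path

    from .cohort import write_metadata

    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    metadata, series = generate_cohort_dataset(config)
    write_metadata(metadata, outdir / "metadata.tsv")
    manifest = []
    for session_id, ts in series.items():
        fname = f"timeseries/{session_id}.tsv"
        ts.to_csv(outdir / fname, sep="\t", index=False, float_format="%.6g")
        manifest.append({"session_id": session_id, "path": fname})
    pd.DataFrame(manifest).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    logger.info("wrote synthetic cohort with %d scans to %s", len(manifest), outdir)
    return metadata


def sample_trajectory_dataset(
    law: MaturationLaw,
    n_subjects: int = 40,
    subject_sd: float = 0.03,
    noise_sd: float = 0.02,
    sex_effect: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Longitudinal response values drawn directly from a maturation law.

    Emulates the trajectory-modelling stage's input without simulating
    time series: each of ``n_subjects`` preterm subjects contributes two
    scans (one shortly after birth, one at term-equivalent age), and the
    response is mu(ga, pma) plus a subject-level random intercept (SD
    ``subject_sd``) plus residual noise (SD ``noise_sd``).

    Birth ages are drawn uniformly over the preterm range rather than
    from the cohort's bell-shaped distribution: the three candidate
    curve shapes only separate when early postmenstrual ages are
    actually observed, so the recovery design covers them evenly.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    ga = rng.uniform(PRETERM_GA_RANGE[0], PRETERM_GA_RANGE[1] - 0.5, n_subjects)
    pma1 = np.minimum(ga + rng.gamma(2.0, 0.75, n_subjects), 36.9)
    pma2 = _truncnorm(rng, 41.2, 1.6, 37.0, 44.0, n_subjects)
    sex = rng.permutation(np.array(["male", "female"] * (n_subjects // 2 + 1))[:n_subjects])
    intercepts = rng.normal(0.0, subject_sd, n_subjects)
    rows = []
    for k in range(n_subjects):
        for ses, pma in enumerate((pma1[k], pma2[k]), start=1):
            mu = law(ga[k], pma) + (sex_effect if sex[k] == "male" else 0.0)
            rows.append(dict(
                subject_id=f"sub-P{k + 1:04d}", session_id=f"sub-P{k + 1:04d}_ses-{ses}",
                ga_birth=float(ga[k]), pma_scan=float(pma), sex=sex[k],
                value=mu + intercepts[k] + rng.normal(0.0, noise_sd),
            ))
    return add_group_column(pd.DataFrame(rows))


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=seed)
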