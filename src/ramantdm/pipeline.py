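"""End-to-end seeded experiments on synthetic urine spectra.

Three experiments mirror the three analyses the package supports:

* ``run_factor_experiment`` — per preparation treatment, generate paired
  untreated/treated calibration series, preprocess, fit PLS on the untreated
  references, predict the treated aliquots and estimate the loss factor.
* ``run_reference_experiment`` — quantify a spiked dilution series in one
  female donor's urine against four reference matrices (own urine, female
  pool, male pool, mixed pool) via difference-spectrum band fitting, and
  compare the resulting detection limits.
* ``run_classification_experiment`` — generate a donor cohort, reduce by
  PCA and score LDA / linear-SVM / radial-SVM sex classification with
  threshold-averaged ROC curves.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .core_io import SpectraSet, Spectrum, median_spectrum
from .errors import StageError
from .peak_quant import (
    build_calibration,
    difference_spectrum,
    fit_marker_band,
    percent_deviation,
    umol_to_mgL,
)
from .preprocess import emsc_correct, normalize, savgol_smooth, snip_baseline, truncate
from .quant_pls import fit_pls_cv, predict_pls
from .sex_classify import cross_validate, pca_reduce, threshold_averaged_roc
from .synthetic_urine import (
    SyntheticConfig,
    generate_classification_cohort,
    generate_factor_experiment,
    make_donor,
    make_pool,
    render_replicates,
    rng_stream,
)
from .treatment_factor import factor_cv

log = logging.getLogger("ramantdm")

#: default spiked-concentration grid for calibration series, uM
DEFAULT_CONCENTRATIONS = (0.0, 100.0, 250.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0)


@dataclass
class PreprocessParams:
    """Parameters of the conditioning chain, defaulting to the standard recipe."""

    truncate_lo: float = 800.0
    truncate_hi: float = 1800.0
    savgol_p: int = 2
    savgol_n: int = 5
    emsc_degree: int = 6
    snip_iterations: int = 20
    snip_order: int = 2
    pls_lo: float = 1150.0
    pls_hi: float = 1750.0
    norm_center: float = 1605.0
    norm_window: float = 15.0


@dataclass
class ExperimentConfig:
    """Serializable description of one experiment run."""

    experiment: str = "factor"  # factor | reference | classification
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    treatments: tuple[str, ...] = ("froz", "filt", "cent", "filt_cent")
    pls_candidates: tuple[int, ...] = (3, 4, 5)
    pls_cv_folds: int = 50
    factor_cv_repeats: int = 10
    classify_cv_repeats: int = 20
    n_pcs: int = 5
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def preprocess_set(spectra: SpectraSet, params: PreprocessParams) -> SpectraSet:
    """Truncate, smooth, EMSC-correct (per-sample median reference) and
    SNIP-baseline every spectrum, preserving the grouping."""
    out: list[Spectrum] = []
    for sample_id, group in spectra.groups():
        stage = f"preprocess:{sample_id}"
        try:
            conditioned = [
                savgol_smooth(
                    truncate(s, params.truncate_lo, params.truncate_hi),
                    params.savgol_p, params.savgol_n,
                )
                for s in group
            ]
            ref = median_spectrum(conditioned)
            corrected = emsc_correct(conditioned, ref, params.emsc_degree)
            for s in corrected:
                _, flat = snip_baseline(
                    s, params.snip_iterations, params.snip_order
                )
                out.append(flat)
        except Exception as exc:  # attach the failing stage
            raise StageError(stage, str(exc)) from exc
    return SpectraSet(out)


def _design_matrix(
    spectra: SpectraSet, lo: float, hi: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vector-normalized spectra in [lo, hi] as rows, plus set concentrations
    and sample-unit group ids."""
    rows, conc, groups = [], [], []
    w = None
    for s in spectra:
        t = normalize(truncate(s, lo, hi), mode="vector")
        if w is None:
            w = t.wavenumbers
        rows.append(t.intensities)
        conc.append(s.meta.concentration_uM)
        groups.append(s.meta.sample_id)
    return np.vstack(rows), np.asarray(conc, float), np.asarray(groups), w


def _report_meta(config: ExperimentConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
    }


def run_factor_experiment(
    config: ExperimentConfig, treatments: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Estimate the loss factor for each treatment from synthetic series.

    Returns one row per treatment: recovered factor (percent), its MAD over
    CV repeats, and the RMSEP before/after correction.
    """
    treatments = treatments or config.treatments
    if len(config.concentrations) < 4:
        raise StageError("config", "need at least 4 concentration levels")
    syn = config.synthetic
    pp = config.preprocess
    rows = []
    for treatment in treatments:
        t0 = time.perf_counter()
        ref_set, trt_set = generate_factor_experiment(
            syn, treatment, list(config.concentrations)
        )
        ref_pp = preprocess_set(ref_set, pp)
        trt_pp = preprocess_set(trt_set, pp)
        X_ref, y_ref, g_ref, _ = _design_matrix(ref_pp, pp.pls_lo, pp.pls_hi)
        X_trt, y_set, _, _ = _design_matrix(trt_pp, pp.pls_lo, pp.pls_hi)
        pls_rng = rng_stream(config.seed, f"pls-cv-{treatment}")
        model = fit_pls_cv(
            X_ref, y_ref, config.pls_candidates, config.pls_cv_folds,
            pls_rng, groups=g_ref,
        )
        c_pred = predict_pls(model, X_trt).values
        fac_rng = rng_stream(config.seed, f"factor-cv-{treatment}")
        est = factor_cv(
            y_set, c_pred, repeats=config.factor_cv_repeats, rng=fac_rng,
            treatment=treatment,
        )
        log.info(
            "factor %s: f=%.4f%% (n_comp=%d, %.1fs)",
            treatment, est.percent, model.n_components,
            time.perf_counter() - t0,
        )
        rows.append(
            {
                "treatment": treatment,
                "factor_percent": est.percent,
                "factor_mad_percent": 100.0 * est.f_mad,
                "rmsep_before_uM": est.rmsep_before,
                "rmsep_after_uM": est.rmsep_after,
                "n": est.n,
                "n_components": model.n_components,
                "true_factor_percent": 100.0 * syn.treatment_factors[treatment],
            }
        )
    df = pd.DataFrame(rows)
    df.attrs.update(_report_meta(config))
    return df


REFERENCE_MATRICES = ("own", "pool_female", "pool_male", "pool_mixed")


def run_reference_experiment(
    config: ExperimentConfig,
    references: tuple[str, ...] = REFERENCE_MATRICES,
) -> pd.DataFrame:
    """Quantify a female-matrix dilution series against each reference matrix.

    For each reference: preprocess, maxima-normalize at ~1605 cm^-1, take
    per-replicate difference spectra against the reference median, fit the
    ~1485 cm^-1 marker band, regress amplitude on concentration and report
    LoD/LoQ (uM and mg/L) plus the percent deviation from the own-matrix LoD.
    """
    syn = config.synthetic
    pp = config.preprocess
    donor_rng = rng_stream(config.seed, "ref-donor")
    own = make_donor(syn, "female", donor_rng, donor_id="patient_f")
    females = [
        make_donor(syn, "female", rng_stream(config.seed, "ref-pool-f", i),
                   donor_id=f"pf{i:02d}")
        for i in range(8)
    ]
    males = [
        make_donor(syn, "male", rng_stream(config.seed, "ref-pool-m", i),
                   donor_id=f"pm{i:02d}")
        for i in range(9)
    ]
    profiles = {
        "own": own,
        "pool_female": make_pool(females, "pool_f"),
        "pool_male": make_pool(males, "pool_m"),
        "pool_mixed": make_pool(females + males, "pool_mix"),
    }

    # spiked dilution series in the patient's own matrix
    spiked: list[Spectrum] = []
    for i, c in enumerate(config.concentrations):
        s_rng = rng_stream(config.seed, "ref-spiked", i)
        spiked += render_replicates(
            own, c, syn, s_rng, syn.replicates_quant,
            sample_id=f"spiked_{i:02d}", role="sample",
        )
    spiked_pp = preprocess_set(SpectraSet(spiked), pp)

    rows = []
    lods: dict[str, float] = {}
    for name in references:
        r_rng = rng_stream(config.seed, f"ref-matrix-{name}")
        ref_spectra = render_replicates(
            profiles[name], 0.0, syn, r_rng, syn.replicates_quant,
            sample_id=f"refmat_{name}", role="reference",
        )
        ref_pp = preprocess_set(SpectraSet(ref_spectra), pp)
        ref_norm = normalize(
            median_spectrum(list(ref_pp)), "max_at", pp.norm_center,
            pp.norm_window,
        )
        conc, amps = [], []
        for s in spiked_pp:
            s_norm = normalize(s, "max_at", pp.norm_center, pp.norm_window)
            diff = difference_spectrum(s_norm, ref_norm)
            fit = fit_marker_band(diff)
            if not fit.converged:
                raise StageError(f"quantify:{name}", fit.message)
            conc.append(s.meta.concentration_uM)
            amps.append(fit.amplitude)
        curve = build_calibration(np.asarray(conc), np.asarray(amps))
        lods[name] = curve.lod_uM
        rows.append(
            {
                "reference": name,
                "lod_uM": curve.lod_uM,
                "lod_mgL": umol_to_mgL(curve.lod_uM),
                "loq_uM": curve.loq_uM,
                "loq_mgL": umol_to_mgL(curve.loq_uM),
                "slope": curve.slope,
                "sigma_n": curve.sigma_n,
                "r_squared": curve.r_squared,
                "n_points": curve.n_points,
            }
        )
    df = pd.DataFrame(rows)
    if "own" in lods:
        df["deviation_percent"] = [
            percent_deviation(l, lods["own"]) if name != "own" and l > 0 else 0.0
            for name, l in zip(df["reference"], df["lod_uM"])
        ]
    df.attrs.update(_report_meta(config))
    return df


CLASSIFIERS = ("lda", "svm_linear", "svm_radial")


def run_classification_experiment(
    config: ExperimentConfig,
    n_female: int = 8,
    n_male: int = 9,
    kinds: tuple[str, ...] = CLASSIFIERS,
    shuffle_labels: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Sex classification on the synthetic cohort.

    Returns a summary table (classifier, AUC mean +- sd over CV repeats) and
    the ROC summaries keyed by classifier.  ``shuffle_labels`` permutes donor
    labels for a null comparison.
    """
    syn = config.synthetic
    pp = config.preprocess
    cohort = generate_classification_cohort(syn, n_female, n_male)
    cohort_pp = preprocess_set(cohort, pp)
    rows_, labels, groups = [], [], []
    for s in cohort_pp:
        t = normalize(s, mode="vector")
        rows_.append(t.intensities)
        labels.append(s.meta.sex)
        groups.append(s.meta.sample_id)
    X = np.vstack(rows_)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if shuffle_labels:
        perm_rng = rng_stream(config.seed, "label-shuffle")
        units = list(dict.fromkeys(groups.tolist()))
        unit_label = {u: labels[groups == u][0] for u in units}
        shuffled = perm_rng.permutation([unit_label[u] for u in units])
        remap = dict(zip(units, shuffled))
        labels = np.asarray([remap[g] for g in groups])
    reduced = pca_reduce(X, n_pcs=config.n_pcs)
    rows, rocs = [], {}
    for kind in kinds:
        cv_rng = rng_stream(config.seed, f"classify-{kind}")
        per_repeat = cross_validate(
            reduced.scores, labels, groups, kind,
            k=config.classify_cv_repeats, rng=cv_rng,
        )
        roc = threshold_averaged_roc(per_repeat, positive="female")
        rocs[kind] = roc
        rows.append(
            {
                "classifier": kind,
                "auc_mean": roc.auc_mean,
                "auc_sd": roc.auc_sd,
                "n_repeats": roc.n_repeats,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs.update(_report_meta(config))
    return df, rocs
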