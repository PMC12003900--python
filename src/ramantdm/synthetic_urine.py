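"""Seeded generator of synthetic urine Raman spectra.

The generator emulates the statistical structure the downstream analyses
assume: a urine matrix dominated by urea, creatinine and uric acid bands
whose intensities vary by donor and sex, a piperacillin contribution exactly
linear in concentration (marker band at ~1485 cm^-1), a smooth polynomial
baseline with a broad hump, per-spectrum affine scatter distortion
(gain, offset), additive Gaussian detector noise, and sample-preparation
treatments that scale the effective drug concentration by (1 - f).

All randomness flows through named seeded streams derived from the config
seed, so regeneration is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_io import SampleMeta, SpectraSet, Spectrum

Band = tuple[float, float, float]  # (center cm^-1, sigma cm^-1, relative intensity)

#: Gaussian band tables per chemical component.  Centers follow the band
#: positions attributable to each metabolite in deep-UV resonance Raman
#: spectra of urine; relative intensities are order-of-magnitude choices.
DEFAULT_BANDS: dict[str, list[Band]] = {
    "urea": [(1015.0, 8.0, 0.60), (1265.0, 8.0, 0.30), (1611.0, 8.0, 1.00)],
    "creatinine": [(850.0, 8.0, 0.70), (1050.0, 8.0, 0.50), (1525.0, 8.0, 0.60)],
    # the weak 1498 band overlaps the piperacillin marker window and is what
    # makes reference-matrix mismatch degrade the band-fit calibration
    "uric_acid": [
        (1355.0, 8.0, 0.50),
        (1435.0, 8.0, 0.60),
        (1498.0, 8.0, 0.25),
        (1660.0, 8.0, 0.80),
    ],
    "piperacillin": [(1140.0, 8.0, 0.30), (1345.0, 8.0, 0.40), (1485.0, 8.0, 1.00)],
}

MATRIX_COMPONENTS = ("urea", "creatinine", "uric_acid")

#: Loss factors f applied by each preparation step: the treated aliquot's
#: effective drug concentration is (1 - f) * spiked concentration.
DEFAULT_TREATMENT_FACTORS: dict[str, float] = {
    "none": 0.0,
    "froz": 0.0842,
    "filt": 0.0236,
    "cent": 0.0280,
    "filt_cent": 0.0505,
}


@dataclass
class ClassStructure:
    """Nonlinear sex geometry for the classification cohort.

    Donors vary along a single composition axis u that trades creatinine
    against uric acid (relative to urea) while keeping the total spectral
    energy constant, so the axis maps onto the spectral manifold without
    the radial warping that vector normalization imposes on other
    composition directions.  Female donors occupy the central interval
    |u| <= female_halfwidth; male donors occupy both flanks
    (male_inner <= |u| <= male_outer).  Because the male class brackets
    the female class on both sides, no linear score can rank the classes
    perfectly, while a boundary radial in u (|u| = const) separates them
    exactly — the geometry that rewards the radial-kernel SVM.
    """

    enabled: bool = True
    center: tuple[float, float] = (0.55, 0.35)  # (cre/urea, uric/urea)
    female_halfwidth: float = 0.012
    male_inner: float = 0.025
    male_outer: float = 0.05


@dataclass
class SyntheticConfig:
    """Full generative description of a synthetic experiment."""

    grid: tuple[float, float, float] = (600.0, 1900.0, 1.0)  # lo, hi, step cm^-1
    band_table: dict[str, list[Band]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_BANDS.items()}
    )
    composition_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "female": {"urea": 600.0, "creatinine": 300.0, "uric_acid": 120.0},
            "male": {"urea": 650.0, "creatinine": 400.0, "uric_acid": 180.0},
        }
    )
    composition_cv: float = 0.05        # donor-to-donor coefficient of variation;
                                        # small vs the sex difference, as implied
                                        # by perfectly discriminable urine pools
    aliquot_cv: float = 0.0             # composition drift between aliquots of
                                        # one homogenized sample (~0 physically)
    drug_response: float = 0.1          # a.u. per uM at unit relative intensity
    baseline_poly: tuple[float, ...] = (60.0, -25.0, 10.0)  # Legendre-type coeffs
    baseline_hump: tuple[float, float, float] = (40.0, 1200.0, 280.0)  # amp, c, sigma
    scatter_gain_sd: float = 0.08
    scatter_offset_sd: float = 4.0
    noise_sd: float = 1.0               # additive detector noise, a.u.
    treatment_factors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_FACTORS)
    )
    treatment_matrix_perturbation: float = 0.0  # off by default
    replicates_quant: int = 3
    replicates_class: int = 20
    class_structure: ClassStructure = field(default_factory=ClassStructure)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, step = self.grid
        if step <= 0 or hi <= lo:
            raise ValueError("grid must satisfy lo < hi and step > 0")
        for name, value in (
            ("composition_cv", self.composition_cv),
            ("aliquot_cv", self.aliquot_cv),
            ("scatter_gain_sd", self.scatter_gain_sd),
            ("scatter_offset_sd", self.scatter_offset_sd),
            ("noise_sd", self.noise_sd),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        for t, f in self.treatment_factors.items():
            if not -1.0 < f < 1.0:
                raise ValueError(f"treatment factor for {t!r} outside (-1, 1)")

    @property
    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DonorProfile:
    """One donor's matrix composition (arbitrary concentration units)."""

    donor_id: str
    sex: str
    component_concentrations: dict[str, float]

    def __post_init__(self) -> None:
        for comp, c in self.component_concentrations.items():
            if c <= 0:
                raise ValueError(f"non-positive concentration for {comp!r}")


def rng_stream(seed: int, name: str, *indices: int) -> np.random.Generator:
    """Named, seeded random stream: independent substream of the config seed."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag, *map(int, indices)])
    )


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Draw from a log-normal with the given arithmetic mean and CV."""
    if cv == 0.0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def make_donor(
    config: SyntheticConfig,
    sex: str,
    rng: np.random.Generator,
    donor_id: str = "donor",
) -> DonorProfile:
    """Draw a donor's matrix composition from sex-specific log-normals."""
    if sex not in ("female", "male"):
        raise ValueError("sex must be 'female' or 'male'")
    means = config.composition_means[sex]
    conc = {
        comp: _lognormal(rng, means[comp], config.composition_cv)
        for comp in MATRIX_COMPONENTS
    }
    return DonorProfile(donor_id, sex, conc)


def make_pool(donors: list[DonorProfile], pool_id: str = "pool") -> DonorProfile:
    """Equal-volume pool: component-wise arithmetic mean of concentrations."""
    if not donors:
        raise ValueError("cannot pool an empty donor list")
    comps = donors[0].component_concentrations.keys()
    conc = {
        c: float(np.mean([d.component_concentrations[c] for d in donors]))
        for c in comps
    }
    sexes = {d.sex for d in donors}
    sex = {"female": "pool_female", "male": "pool_male"}.get(
        sexes.pop() if len(sexes) == 1 else "", "pool_mixed"
    )
    return DonorProfile(pool_id, sex, conc)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _band_profile(w: np.ndarray, bands: list[Band]) -> np.ndarray:
    out = np.zeros_like(w)
    for center, sigma, rel in bands:
        out += rel * np.exp(-0.5 * ((w - center) / sigma) ** 2)
    return out


def matrix_signal(
    profile: DonorProfile, config: SyntheticConfig, w: np.ndarray | None = None
) -> np.ndarray:
    """Noise-free matrix contribution (no drug, no baseline)."""
    if w is None:
        w = config.wavenumbers
    signal = np.zeros_like(w)
    for comp in MATRIX_COMPONENTS:
        signal += profile.component_concentrations[comp] * _band_profile(
            w, config.band_table[comp]
        )
    return signal


def drug_signal(drug_uM: float, config: SyntheticConfig,
                w: np.ndarray | None = None) -> np.ndarray:
    """Noise-free piperacillin contribution, exactly linear in concentration."""
    if w is None:
        w = config.wavenumbers
    return drug_uM * config.drug_response * _band_profile(
        w, config.band_table["piperacillin"]
    )


def _baseline(config: SyntheticConfig, w: np.ndarray) -> np.ndarray:
    wt = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
    base = np.polynomial.legendre.legval(wt, np.asarray(config.baseline_poly))
    amp, center, sigma = config.baseline_hump
    return base + amp * np.exp(-0.5 * ((w - center) / sigma) ** 2)


def render_spectrum(
    profile: DonorProfile,
    drug_uM: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    meta: SampleMeta | None = None,
) -> Spectrum:
    """Render one spectrum from the forward model.

    intensity = gain * (matrix + drug + baseline) + offset + noise, where
    gain ~ 1 + N(0, scatter_gain_sd), offset ~ N(0, scatter_offset_sd) and
    the noise is i.i.d. Gaussian per channel.  With all stochastic terms set
    to zero the output is the closed-form band mixture.
    """
    if drug_uM < 0:
        raise ValueError("drug concentration must be >= 0")
    w = config.wavenumbers
    clean = matrix_signal(profile, config, w) + drug_signal(drug_uM, config, w)
    clean = clean + _baseline(config, w)
    gain = 1.0 + (rng.normal(0.0, config.scatter_gain_sd)
                  if config.scatter_gain_sd > 0 else 0.0)
    gain = max(gain, 0.05)
    offset = (rng.normal(0.0, config.scatter_offset_sd)
              if config.scatter_offset_sd > 0 else 0.0)
    noise = (rng.normal(0.0, config.noise_sd, size=w.size)
             if config.noise_sd > 0 else 0.0)
    intensity = gain * clean + offset + noise
    if meta is None:
        meta = SampleMeta(sample_id=profile.donor_id, sex=profile.sex,
                          concentration_uM=drug_uM)
    return Spectrum(w.copy(), intensity, meta)


def _jitter_profile(
    profile: DonorProfile, cv: float, rng: np.random.Generator
) -> DonorProfile:
    if cv == 0.0:
        return profile
    conc = {
        k: _lognormal(rng, v, cv)
        for k, v in profile.component_concentrations.items()
    }
    return DonorProfile(profile.donor_id, profile.sex, conc)


def render_replicates(
    profile: DonorProfile,
    drug_uM: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    n_replicates: int,
    sample_id: str,
    treatment: str = "none",
    role: str = "sample",
    set_concentration_uM: float | None = None,
) -> list[Spectrum]:
    """Render replicate measurements of one physical aliquot.

    The aliquot shares one composition jitter draw; scatter and noise are
    redrawn per replicate.  ``set_concentration_uM`` is what gets recorded in
    the metadata (the *spiked* value), which may differ from the effective
    ``drug_uM`` after a treatment loss.
    """
    aliquot = _jitter_profile(profile, config.aliquot_cv, rng)
    recorded = drug_uM if set_concentration_uM is None else set_concentration_uM
    out = []
    for r in range(1, n_replicates + 1):
        meta = SampleMeta(
            sample_id=sample_id,
            sex=aliquot.sex,
            treatment=treatment,
            concentration_uM=recorded,
            replicate=r,
            role=role,
        )
        out.append(render_spectrum(aliquot, drug_uM, config, rng, meta))
    return out


# ---------------------------------------------------------------------------
# experiment-level generators
# ---------------------------------------------------------------------------

def generate_factor_experiment(
    config: SyntheticConfig,
    treatment: str,
    concentrations: list[float],
) -> tuple[SpectraSet, SpectraSet]:
    """Paired calibration series for one sample-preparation treatment.

    Reference samples are treated first and spiked after, so their effective
    concentration equals the set value; treated samples are spiked before
    treatment, so their effective concentration is (1 - f) * set value.
    Both series use the same female donor matrix.
    """
    if treatment not in config.treatment_factors:
        raise KeyError(f"unknown treatment {treatment!r}")
    f = config.treatment_factors[treatment]
    donor_rng = rng_stream(config.seed, "factor-donor")
    donor = make_donor(config, "female", donor_rng, donor_id="cal_donor")
    reference, treated = [], []
    for i, c in enumerate(concentrations):
        ref_rng = rng_stream(config.seed, f"factor-ref-{treatment}", i)
        trt_rng = rng_stream(config.seed, f"factor-trt-{treatment}", i)
        reference += render_replicates(
            donor, c, config, ref_rng, config.replicates_quant,
            sample_id=f"ref_{treatment}_{i:02d}", treatment=treatment,
            role="reference",
        )
        treated += render_replicates(
            donor, (1.0 - f) * c, config, trt_rng, config.replicates_quant,
            sample_id=f"trt_{treatment}_{i:02d}", treatment=treatment,
            role="sample", set_concentration_uM=c,
        )
    return SpectraSet(reference), SpectraSet(treated)


def _band_energy(bands: list[Band], lo: float = 800.0, hi: float = 1800.0) -> float:
    """Sum of squared relative band intensities within [lo, hi]."""
    return float(sum(rel * rel for c, _, rel in bands if lo <= c <= hi))


def _neutral_direction(
    config: SyntheticConfig, structure: ClassStructure
) -> np.ndarray:
    """Unit direction in (cre/urea, uric/urea) space along which the total
    spectral energy is constant to first order at the structure center."""
    cx, cy = structure.center
    e_c = _band_energy(config.band_table["creatinine"])
    e_u = _band_energy(config.band_table["uric_acid"])
    d = np.array([1.0, -(cx * e_c) / (cy * e_u)])
    return d / np.linalg.norm(d)


def _structured_ratios(
    sex: str,
    index: int,
    n_of_sex: int,
    structure: ClassStructure,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Place one donor on the norm-neutral composition axis.

    Positions are stratified evenly within each class segment (with
    jitter), so small cohorts already cover their segments; male donors
    alternate between the low-u and high-u flank.
    """
    fh, mi, mo = (structure.female_halfwidth, structure.male_inner,
                  structure.male_outer)
    if sex == "female":
        slots = n_of_sex
        u = -fh + 2.0 * fh * (index + 0.5 + rng.uniform(-0.3, 0.3)) / slots
    else:
        side = -1.0 if index % 2 == 0 else 1.0
        slot = index // 2
        slots = (n_of_sex + 1) // 2 if index % 2 == 0 else n_of_sex // 2
        u = side * (mi + (mo - mi) * (slot + 0.5 + rng.uniform(-0.3, 0.3))
                    / max(slots, 1))
    cx, cy = structure.center
    direction = _neutral_direction(config, structure)
    r1 = max(cx + u * direction[0], 0.02)
    r2 = max(cy + u * direction[1], 0.02)
    return r1, r2


def generate_classification_cohort(
    config: SyntheticConfig, n_female: int = 8, n_male: int = 9
) -> SpectraSet:
    """Cohort of donors with ``replicates_class`` spectra each.

    With the nonlinear class structure enabled (default), the sexes are
    separable by a radial boundary in the plane of the creatinine/urea and
    uric-acid/urea composition ratios but not by any linear one.  With the
    structure disabled, donors are drawn straight from the sex-specific
    composition distributions.
    """
    if n_female < 1 or n_male < 1:
        raise ValueError("need at least one donor per sex")
    spectra: list[Spectrum] = []
    for sex, n in (("female", n_female), ("male", n_male)):
        for i in range(n):
            d_rng = rng_stream(config.seed, f"cohort-{sex}", i)
            donor = make_donor(config, sex, d_rng, donor_id=f"{sex[0]}{i:02d}")
            if config.class_structure.enabled:
                r1, r2 = _structured_ratios(
                    sex, i, n, config.class_structure, config, d_rng
                )
                urea = donor.component_concentrations["urea"]
                donor = DonorProfile(
                    donor.donor_id, sex,
                    {"urea": urea, "creatinine": r1 * urea, "uric_acid": r2 * urea},
                )
            s_rng = rng_stream(config.seed, f"cohort-spectra-{sex}", i)
            spectra += render_replicates(
                donor, 0.0, config, s_rng, config.replicates_class,
                sample_id=donor.donor_id, role="sample",
            )
    return SpectraSet(spectra)
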