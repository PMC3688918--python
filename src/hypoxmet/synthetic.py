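"""Seeded generator of injection-level datasets emulating a two-class
UPLC-QTOFMS retina-hypoxia profiling experiment.

The default configuration reproduces the study design this pipeline targets:
5 hypoxic + 5 normoxic biological samples measured in triplicate plus 7
solvent blanks (37 injections), 365 aligned features of which 136 are
blank-borne background contaminants and 117 are low-frequency markers
(detected in fewer than 3 collapsed samples), leaving 112 reliable features,
8 of which carry a planted class effect. Feature abundances are log-normal
with multiplicative replicate noise calibrated to a 14% internal-standard
area RSD; missingness follows a limit-of-detection-like logistic dropout in
log abundance; the internal-standard m/z is jittered within +/-10 ppm per
injection.

The planted discriminant features carry the retention-time/m/z identities of
the study's reported markers (CDP-choline at 489.1157 and its sodium adduct
at 511.0977 elevated under hypoxia; pyroglutamic acid, its in-source
fragment, CDP-DG, GSSG and two unidentified ions elevated under normoxia),
so annotation and direction-recovery tests can address them by id.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError
from .io import (
    CLASS_HYPOXIA,
    CLASS_NORMOXIA,
    ROLE_BLANK,
    ROLE_SAMPLE,
    FeatureDescriptor,
    InjectionRecord,
    InjectionTable,
    canonical_feature_id,
)

#: Reserpine internal standard m/z.
IS_REFERENCE_MZ = 609.2812

# (rt [min], m/z, tag, direction): +1 = elevated in hypoxia, -1 = elevated
# in normoxia. Identities mirror the reported discriminant markers.
PLANTED_CATALOG = [
    (0.69, 489.1157, "cdp_choline", +1),
    (0.69, 511.0977, "cdp_choline_na", +1),
    (0.57, 84.0451, "pyroglutamic_fragment", -1),
    (0.57, 130.0506, "pyroglutamic", -1),
    (0.53, 201.9340, "unknown_201", -1),
    (0.54, 222.0302, "unknown_222", -1),
    (0.53, 364.9069, "cdp_dg_na", -1),
    (0.77, 613.1588, "gssg", -1),
]


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters of the synthetic generator.

    Counts mirror the emulated design; noise parameters are in natural-log
    intensity units unless stated otherwise.
    """

    n_per_class: tuple = (5, 5)
    n_replicates: int = 3
    n_blanks: int = 7
    n_features: int = 365
    n_blank_features: int = 136
    n_lowfreq_features: int = 117
    n_discriminant: int = 8
    #: planted per-feature |log2 fold change| between classes
    effect_size: float = 2.0
    base_intensity_logmean: float = 8.5
    base_intensity_logsd: float = 1.0
    #: between-sample biological variability (ln scale)
    bio_logsd: float = 0.15
    #: sd of the per-feature loadings on the latent physiological response
    #: score; gives the collinear, metabolome-wide class-correlated
    #: covariance that lets one principal component carry the class split
    response_logsd: float = 0.25
    #: within-class sd of the latent physiological response score
    response_noise: float = 0.25
    #: between-class shift of the response score; 0 with n_discriminant=0
    #: gives an exchangeable (null) dataset that keeps the collinearity
    response_class_shift: float = 1.0
    #: target replicate/IS area relative standard deviation, percent
    is_rsd_target: float = 14.0
    #: detection limit sits this many ln units below the mean abundance
    lod_logoffset: float = 2.2
    lod_logscale: float = 1.0
    #: probability a background (blank-borne) feature shows up in a sample
    blank_sample_detect_prob: float = 0.95
    blank_blank_detect_prob: float = 0.9
    #: ceiling on the per-cell chance of losing one replicate; the actual
    #: probability is this times the logistic dropout at the cell's abundance
    replicate_dropout_max: float = 0.5
    #: probability an undetected cell still shows one stray replicate
    stray_replicate_prob: float = 0.05
    is_area_mean: float = 2.0e4
    mz_jitter_ppm: float = 10.0

    def __post_init__(self):
        if any(c < 0 for c in asdict_counts(self)):
            raise ConfigurationError("counts must be non-negative")
        if self.n_blank_features + self.n_lowfreq_features > self.n_features:
            raise ConfigurationError(
                "blank + low-frequency feature counts exceed n_features"
            )
        if self.n_discriminant > self.n_retained:
            raise ConfigurationError(
                "more discriminant features than retained features"
            )

    @property
    def n_retained(self) -> int:
        return self.n_features - self.n_blank_features - self.n_lowfreq_features

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_class))

    @property
    def replicate_logsd(self) -> float:
        """ln-scale sigma giving the configured area RSD for log-normal noise."""
        rsd = self.is_rsd_target / 100.0
        return math.sqrt(math.log1p(rsd * rsd))


def asdict_counts(cfg) -> list[int]:
    return [
        cfg.n_replicates,
        cfg.n_blanks,
        cfg.n_features,
        cfg.n_blank_features,
        cfg.n_lowfreq_features,
        cfg.n_discriminant,
    ]


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    discriminant_ids: list[str]
    #: feature_id -> +1 (up in hypoxia) or -1 (up in normoxia)
    directions: dict[str, int]
    blank_feature_ids: list[str]
    lowfreq_feature_ids: list[str]
    sample_ids: list[str]
    class_labels: list[str]

    def to_dict(self) -> dict:
        return asdict(self)


def _random_features(rng, n, used_ids):
    """Draw n distinct (rt, mz) descriptors avoiding ids already used."""
    out = []
    while len(out) < n:
        rt = float(np.round(rng.uniform(0.3, 14.0), 2))
        mz = float(np.round(rng.uniform(50.0, 950.0), 4))
        fid = canonical_feature_id(rt, mz)
        if fid in used_ids:
            continue
        used_ids.add(fid)
        out.append(FeatureDescriptor(fid, rt, mz))
    return out


def generate(config: GeneratorConfig | None = None, seed: int = 0):
    """Generate one synthetic injection-level dataset.

    Returns ``(InjectionTable, GroundTruth)``. Fully deterministic given
    ``(config, seed)``. Feature categories are exact by construction: the
    ``n_blank_features`` background features are the only ones detected in
    blank injections, low-frequency features yield a nonzero replicate
    median in at most 2 samples, and every retained feature in at least 3 —
    so the blank-removal and frequency filters reproduce the configured
    365 -> 229 -> 112 trajectory.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)

    n_h, n_n = cfg.n_per_class
    ns, reps, nb = cfg.n_samples, cfg.n_replicates, cfg.n_blanks
    sample_ids = [f"H{i+1}" for i in range(n_h)] + [f"N{i+1}" for i in range(n_n)]
    class_labels = [CLASS_HYPOXIA] * n_h + [CLASS_NORMOXIA] * n_n
    hyp_mask = np.array([c == CLASS_HYPOXIA for c in class_labels])

    # --- feature descriptors -------------------------------------------------
    used: set[str] = set()
    planted = []
    directions: dict[str, int] = {}
    for rt, mz, _tag, direction in PLANTED_CATALOG[: cfg.n_discriminant]:
        fid = canonical_feature_id(rt, mz)
        used.add(fid)
        planted.append(FeatureDescriptor(fid, rt, mz))
        directions[fid] = direction
    extra = cfg.n_discriminant - len(planted)
    if extra > 0:  # beyond the catalog: alternate directions
        more = _random_features(rng, extra, used)
        for k, f in enumerate(more):
            directions[f.feature_id] = 1 if k % 2 == 0 else -1
        planted += more

    retained = planted + _random_features(rng, cfg.n_retained - len(planted), used)
    lowfreq = _random_features(rng, cfg.n_lowfreq_features, used)
    blankf = _random_features(rng, cfg.n_blank_features, used)
    features = retained + lowfreq + blankf
    nf = len(features)

    # --- per-feature base abundance and sample-level detection ---------------
    ln_base = rng.normal(cfg.base_intensity_logmean, cfg.base_intensity_logsd, nf)
    # low-frequency markers sit near the detection limit
    lo0 = cfg.n_retained
    ln_base[lo0 : lo0 + cfg.n_lowfreq_features] -= 2.0

    detected = np.zeros((nf, ns), dtype=bool)
    lod = cfg.base_intensity_logmean - cfg.lod_logoffset
    p_det = 1.0 / (1.0 + np.exp(-(ln_base - lod) / cfg.lod_logscale))
    for j in range(cfg.n_retained):
        if j < cfg.n_discriminant:
            detected[j, :] = True  # planted effects are always observed
            continue
        k = max(3, int(rng.binomial(ns, p_det[j])))
        detected[j, rng.choice(ns, size=min(k, ns), replace=False)] = True
    for j in range(lo0, lo0 + cfg.n_lowfreq_features):
        k = int(rng.integers(1, 3))  # detected in 1 or 2 samples only
        detected[j, rng.choice(ns, size=k, replace=False)] = True
    b0 = lo0 + cfg.n_lowfreq_features
    for j in range(b0, nf):
        detected[j, :] = rng.random(ns) < cfg.blank_sample_detect_prob

    # --- sample-level expected intensities -----------------------------------
    ln_val = ln_base[:, None] + rng.normal(0.0, cfg.bio_logsd, (nf, ns))

    # metabolome-wide response: every reliable metabolite loads weakly (and
    # with random sign) on one latent physiological score that differs
    # between classes — the collinear structure that aligns a dominant PC
    # with the class split without creating strong single-feature markers
    half = 0.5 * cfg.response_class_shift
    r_score = np.where(hyp_mask, half, -half) + rng.normal(0.0, cfg.response_noise, ns)
    n_bg = cfg.n_retained - cfg.n_discriminant
    gamma = rng.normal(0.0, cfg.response_logsd, n_bg)
    ln_val[cfg.n_discriminant : cfg.n_retained] += gamma[:, None] * r_score[None, :]

    effect_ln = cfg.effect_size * math.log(2.0)
    for j, f in enumerate(retained[: cfg.n_discriminant]):
        up = hyp_mask if directions[f.feature_id] > 0 else ~hyp_mask
        ln_val[j, up] += effect_ln

    # --- replicate expansion --------------------------------------------------
    sig_rep = cfg.replicate_logsd
    rep_noise = rng.normal(0.0, sig_rep, (nf, ns, reps))
    values = np.exp(ln_val[:, :, None] + rep_noise)
    values[~detected, :] = 0.0

    # detected cells: at most one replicate may drop out (median stays > 0);
    # dropout is a limit-of-detection mechanism, logistic in log abundance,
    # so abundant features essentially never lose replicates
    p_cell_det = 1.0 / (1.0 + np.exp(-(ln_val - lod) / cfg.lod_logscale))
    drop = rng.random((nf, ns)) < cfg.replicate_dropout_max * (1.0 - p_cell_det)
    drop &= detected
    which = rng.integers(0, reps, (nf, ns))
    fj, sj = np.where(drop)
    values[fj, sj, which[fj, sj]] = 0.0

    # undetected cells: occasionally one stray low replicate (median stays 0)
    if reps >= 3:
        stray = (rng.random((nf, ns)) < cfg.stray_replicate_prob) & ~detected
        fj, sj = np.where(stray)
        values[fj, sj, which[fj, sj]] = np.exp(
            ln_base[fj] - cfg.lod_logoffset + rng.normal(0, sig_rep, fj.size)
        )

    # --- blank injections -----------------------------------------------------
    blank_vals = np.zeros((nf, nb))
    det_blank = rng.random((cfg.n_blank_features, nb)) < cfg.blank_blank_detect_prob
    for r in range(cfg.n_blank_features):  # every background feature hits >=1 blank
        if not det_blank[r].any():
            det_blank[r, rng.integers(0, nb)] = True
    blank_noise = rng.normal(0.0, sig_rep, (cfg.n_blank_features, nb))
    blank_vals[b0:, :] = np.where(
        det_blank, np.exp(ln_base[b0:, None] + blank_noise), 0.0
    )

    # --- assemble the injection table -----------------------------------------
    intensity = np.concatenate([values.reshape(nf, ns * reps), blank_vals], axis=1)

    records = []
    n_inj = ns * reps + nb
    run_order = rng.permutation(n_inj) + 1
    k = 0
    for s, sid in enumerate(sample_ids):
        for r in range(reps):
            records.append(
                InjectionRecord(
                    injection_id=f"{sid}_r{r+1}",
                    sample_id=sid,
                    replicate_index=r + 1,
                    role=ROLE_SAMPLE,
                    class_label=class_labels[s],
                    run_order=int(run_order[k]),
                )
            )
            k += 1
    for b in range(nb):
        records.append(
            InjectionRecord(
                injection_id=f"B{b+1}",
                sample_id=None,
                replicate_index=1,
                role=ROLE_BLANK,
                class_label=None,
                run_order=int(run_order[k]),
            )
        )
        k += 1

    is_sigma = cfg.replicate_logsd
    is_area = np.exp(rng.normal(math.log(cfg.is_area_mean), is_sigma, n_inj))
    is_mz = IS_REFERENCE_MZ * (
        1.0 + rng.uniform(-cfg.mz_jitter_ppm, cfg.mz_jitter_ppm, n_inj) * 1e-6
    )

    table = InjectionTable(
        features=features,
        injections=records,
        intensity=np.round(intensity, 6),
        is_area=is_area,
        is_mz=is_mz,
    )
    truth = GroundTruth(
        discriminant_ids=[f.feature_id for f in planted],
        directions=directions,
        blank_feature_ids=[f.feature_id for f in blankf],
        lowfreq_feature_ids=[f.feature_id for f in lowfreq],
        sample_ids=sample_ids,
        class_labels=class_labels,
    )
    return table, truth


def paper_shape_fixture(seed: int = 0):
    """A default-configuration instance whose preprocessing trajectory is
    365 -> 229 -> 112 features by construction (10 samples, 37 injections)."""
    return generate(GeneratorConfig(), seed=seed)
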