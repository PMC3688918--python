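"""Putative annotation of profiling features by accurate mass.

Observed feature m/z values are matched against theoretical positive-mode
ions of a compound list — protonated molecules [M+H]+, sodium adducts
[M+Na]+ and configurable neutral losses such as the formic-acid loss
[M+H-CH2O2]+ typical of pyroglutamic acid in-source fragmentation — within
a +/-5 mDa spectral mass tolerance by default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .errors import ValidationError
from .io import FeatureDescriptor

PROTON_MASS = 1.00728
SODIUM_ADDUCT_MASS = 22.98922  # [M+Na]+ minus M
#: neutral-loss table (name -> mass in Da), user-extensible
NEUTRAL_LOSSES = {"CH2O2": 46.00548}


@dataclass(frozen=True)
class CompoundRecord:
    """A candidate metabolite: name and monoisotopic mass in Da."""

    name: str
    monoisotopic_mass: float

    def __post_init__(self):
        if self.monoisotopic_mass <= 0:
            raise ValidationError(f"non-positive mass for {self.name}")


@dataclass(frozen=True)
class IonRule:
    """An ionization/fragmentation rule: theoretical m/z = mass + shift."""

    label: str
    shift: float


def default_ion_rules(neutral_losses=None) -> list[IonRule]:
    rules = [
        IonRule("[M+H]+", PROTON_MASS),
        IonRule("[M+Na]+", SODIUM_ADDUCT_MASS),
    ]
    for name, mass in (neutral_losses or NEUTRAL_LOSSES).items():
        rules.append(IonRule(f"[M+H-{name}]+", PROTON_MASS - mass))
    return rules


@dataclass
class AnnotationMatch:
    feature_id: str
    observed_mz: float
    compound: str
    ion: str
    theoretical_mz: float
    delta_mda: float  # signed, observed - theoretical, in mDa


@dataclass
class AnnotationResult:
    matches: list[AnnotationMatch]
    unidentified_feature_ids: list[str]

    def to_dict(self) -> dict:
        return {
            "matches": [asdict(m) for m in self.matches],
            "unidentified_feature_ids": list(self.unidentified_feature_ids),
        }


def annotate(
    features,
    compounds,
    tol_mda: float = 5.0,
    ion_rules=None,
) -> AnnotationResult:
    """Match features to compound ions within ``tol_mda`` milli-Daltons.

    Every (feature, compound, ion rule) combination with
    ``|observed - theoretical| <= tol_mda/1000`` is reported with its signed
    mDa error; features with no match at all are flagged unidentified.
    Shrinking the tolerance can only remove matches, never add them.
    """
    if tol_mda <= 0:
        raise ValidationError("tolerance must be positive")
    rules = ion_rules if ion_rules is not None else default_ion_rules()
    matches = []
    unidentified = []
    for f in features:
        mz = f.mz if isinstance(f, FeatureDescriptor) else float(f[1])
        fid = f.feature_id if isinstance(f, FeatureDescriptor) else str(f[0])
        hit = False
        for c in compounds:
            for rule in rules:
                theo = c.monoisotopic_mass + rule.shift
                delta = mz - theo
                if abs(delta) <= tol_mda / 1000.0 + 1e-12:
                    matches.append(
                        AnnotationMatch(
                            feature_id=fid,
                            observed_mz=mz,
                            compound=c.name,
                            ion=rule.label,
                            theoretical_mz=theo,
                            delta_mda=delta * 1000.0,
                        )
                    )
                    hit = True
        if not hit:
            unidentified.append(fid)
    return AnnotationResult(matches=matches, unidentified_feature_ids=unidentified)


def link_in_source_fragments(features, tol_mda: float = 5.0, losses=None):
    """Pair features whose m/z difference equals a neutral-loss mass.

    Returns ``[(parent_feature_id, fragment_feature_id, loss_name,
    delta_mda)]`` for co-eluting pairs (same nominal retention time window
    is the caller's concern; all pairs are reported).
    """
    losses = losses or NEUTRAL_LOSSES
    out = []
    feats = list(features)
    for i, fa in enumerate(feats):
        for fb in feats:
            if fa is fb:
                continue
            diff = fa.mz - fb.mz
            for name, mass in losses.items():
                delta = diff - mass
                if abs(delta) <= tol_mda / 1000.0 + 1e-12:
                    out.append((fa.feature_id, fb.feature_id, name, delta * 1000.0))
    return out
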