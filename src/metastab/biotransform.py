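"""Mass-shift biotransformation annotation and fragment-based site localization.

Phase-I metabolism of the studied arylpiperazines shows up in LC-MS as a
small vocabulary of characteristic mass shifts between the metabolite and
parent [M+H]+ ions:

==============================  =======  ==================  =============
reaction                        nominal  elemental change    monoisotopic
==============================  =======  ==================  =============
hydroxylation                    +16 Da  +O                   +15.9949 Da
double hydroxylation             +32 Da  +2O                  +31.9898 Da
water addition + ring reduction  +34 Da  +H2O +O              +34.0055 Da
O-demethylation                  -14 Da  -CH2                 -14.0157 Da
O-demethylation + hydroxylation   +2 Da  -CH2 +O               +1.9793 Da
==============================  =======  ==================  =============

Nominal (whole-Da) shifts are the primary matching currency when the mass
tolerance is given in Da; monoisotopic shifts computed from the elemental
change are used for ppm tolerances.  Rules can also be combined (unordered
multisets of depth <= 2) to explain composite shifts.

Site localization follows fragment-ion reasoning: given parent/metabolite
m/z pairs for labeled fragments tagged with the substructures they cover
(pharmacophore arylpiperazine head, linker chain, non-pharmacophore
pyrido-pyrimidinedione system), the modification site is the class present
in every mass-shifted fragment and absent from every unshifted one.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "BiotransformationRule",
    "FeatureIon",
    "MetaboliteAnnotation",
    "FragmentObservation",
    "LocalizationResult",
    "Tolerance",
    "BiotransformError",
    "MONOISOTOPIC_MASS",
    "formula_delta_mass",
    "builtin_rules",
    "annotate",
    "localize",
]

#: Monoisotopic masses of the elements appearing in the rule vocabulary.
MONOISOTOPIC_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}


class BiotransformError(ValueError):
    pass


def formula_delta_mass(delta: dict[str, int]) -> float:
    """Monoisotopic mass of an elemental change, e.g. {"C": -1, "H": -2}."""
    try:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in delta.items())
    except KeyError as exc:
        raise BiotransformError(f"unknown element {exc.args[0]!r}") from None


def _format_delta(delta: dict[str, int]) -> str:
    parts = []
    for el in sorted(delta):
        n = delta[el]
        if n == 0:
            continue
        parts.append(f"{'+' if n > 0 else '-'}{el}{abs(n) if abs(n) > 1 else ''}")
    return "".join(parts) or "none"


@dataclass(frozen=True)
class BiotransformationRule:
    """One biotransformation type, identified by its mass shift."""

    name: str
    nominal_shift: int
    elemental_change: dict[str, int] = field(compare=False)
    site_class: str = "any"

    def __post_init__(self):
        if self.site_class not in ("pharmacophore", "non-pharmacophore", "any"):
            raise BiotransformError(f"unknown site class {self.site_class!r}")
        mono = self.monoisotopic_shift
        if abs(mono - self.nominal_shift) >= 0.5:
            raise BiotransformError(
                f"rule {self.name!r}: monoisotopic shift {mono:.4f} is more than "
                f"0.5 Da from nominal {self.nominal_shift}"
            )

    @property
    def monoisotopic_shift(self) -> float:
        return formula_delta_mass(self.elemental_change)

    @property
    def formula(self) -> str:
        return _format_delta(self.elemental_change)


def builtin_rules() -> list[BiotransformationRule]:
    """The five built-in biotransformation rules of the arylpiperazine panel.

    O-demethylation is encoded as -CH2 / -14 Da (loss of the methyl carbon
    with two hydrogens, the OH staying on the molecule); the "+34" rule's
    elemental change +H2O +O reproduces its nominal shift without asserting
    a mechanism.
    """
    return [
        BiotransformationRule("hydroxylation", 16, {"O": 1}, "any"),
        BiotransformationRule("double hydroxylation", 32, {"O": 2}, "any"),
        BiotransformationRule(
            "water addition + ring reduction", 34, {"H": 2, "O": 2},
            "non-pharmacophore",
        ),
        BiotransformationRule("O-demethylation", -14, {"C": -1, "H": -2},
                              "non-pharmacophore"),
        BiotransformationRule(
            "O-demethylation + hydroxylation", 2, {"C": -1, "H": -2, "O": 1}, "any"
        ),
    ]


@dataclass(frozen=True)
class FeatureIon:
    mz: float
    rt: float
    intensity: float = 0.0

    def __post_init__(self):
        if self.mz <= 0:
            raise BiotransformError("m/z must be positive")
        if self.intensity < 0:
            raise BiotransformError("intensity must be nonnegative")


@dataclass
class MetaboliteAnnotation:
    parent_id: str
    feature: FeatureIon
    rules: tuple[BiotransformationRule, ...]
    observed_shift: float
    error_da: float
    error_ppm: float
    rt_earlier_than_parent: bool

    @property
    def rule_names(self) -> str:
        return " + ".join(r.name for r in self.rules)


@dataclass(frozen=True)
class Tolerance:
    """A mass tolerance: value plus unit ('Da' or 'ppm')."""

    value: float
    unit: str

    def __post_init__(self):
        if self.unit not in ("Da", "ppm"):
            raise BiotransformError(f"tolerance unit must be Da or ppm, got {self.unit!r}")
        if self.value <= 0:
            raise BiotransformError("tolerance must be > 0")

    @classmethod
    def parse(cls, text: "Tolerance | str | float") -> "Tolerance":
        """Parse '0.05Da', '10ppm' or a bare number (interpreted as Da)."""
        if isinstance(text, Tolerance):
            return text
        if isinstance(text, (int, float)):
            return cls(float(text), "Da")
        m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*(Da|ppm)\s*", str(text))
        if m is None:
            raise BiotransformError(f"cannot parse tolerance {text!r}")
        return cls(float(m.group(1)), m.group(2))

    def window_da(self, mz: float) -> float:
        return self.value if self.unit == "Da" else self.value * 1e-6 * mz


def _candidate_combinations(
    rules: list[BiotransformationRule], max_combination: int
):
    """Single rules plus unordered multisets up to the combination depth."""
    for depth in range(1, max_combination + 1):
        for combo in itertools.combinations_with_replacement(rules, depth):
            yield combo


def annotate(
    parent_id: str,
    parent_mz: float,
    parent_rt: float,
    features: list[FeatureIon],
    tolerance: Tolerance | str | float = "0.05Da",
    rules: list[BiotransformationRule] | None = None,
    max_combination: int = 2,
) -> tuple[list[MetaboliteAnnotation], list[FeatureIon]]:
    """Assign biotransformation types to metabolite features by mass shift.

    For each feature the observed shift is its m/z minus the parent [M+H]+
    m/z, compared against every single rule and unordered rule pair.  With
    a Da tolerance the comparison uses nominal shifts; with a ppm tolerance
    it uses monoisotopic shifts.  Matches are returned sorted per feature
    by absolute mass error, then by fewest constituent rules; features with
    no match land in the ``unassigned`` list.  A feature eluting before the
    parent gets an informational flag (hydroxylated metabolites are more
    hydrophilic), never a rejection.
    """
    tol = Tolerance.parse(tolerance)
    rules = rules if rules is not None else builtin_rules()
    annotations: list[MetaboliteAnnotation] = []
    unassigned: list[FeatureIon] = []
    for feat in features:
        observed = feat.mz - parent_mz
        window = tol.window_da(feat.mz)
        matches = []
        for combo in _candidate_combinations(rules, max_combination):
            nominal = sum(r.nominal_shift for r in combo)
            mono = sum(r.monoisotopic_shift for r in combo)
            expected = nominal if tol.unit == "Da" else mono
            err = observed - expected
            if abs(err) <= window:
                matches.append(
                    MetaboliteAnnotation(
                        parent_id,
                        feat,
                        combo,
                        observed,
                        observed - mono,
                        (observed - mono) / feat.mz * 1e6,
                        feat.rt < parent_rt,
                    )
                )
        if matches:
            matches.sort(
                key=lambda a: (
                    abs(a.observed_shift - (
                        sum(r.nominal_shift for r in a.rules)
                        if tol.unit == "Da"
                        else sum(r.monoisotopic_shift for r in a.rules)
                    )),
                    len(a.rules),
                )
            )
            annotations.extend(matches)
        else:
            unassigned.append(feat)
    return annotations, unassigned


@dataclass(frozen=True)
class FragmentObservation:
    """A labeled fragment ion observed in both parent and metabolite spectra."""

    label: str
    parent_mz: float
    metabolite_mz: float
    tags: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "tags", frozenset(self.tags))
        if not self.tags:
            raise BiotransformError(f"fragment {self.label!r} has no substructure tags")

    @property
    def shift(self) -> float:
        return self.metabolite_mz - self.parent_mz


@dataclass
class LocalizationResult:
    site_classes: frozenset[str]
    conclusive: bool
    shifted: list[str]
    unshifted: list[str]
    unexplained: list[str]
    explanation: str


def localize(
    fragments: list[FragmentObservation],
    delta_m: float,
    tolerance: Tolerance | str | float = "0.05Da",
) -> LocalizationResult:
    """Localize a modification from parent/metabolite fragment mass shifts.

    Fragments are partitioned into shifted (fragment shift within tolerance
    of the metabolite's overall shift) and unshifted (shift within
    tolerance of zero).  The modification site is the set of substructure
    classes carried by every shifted fragment and by no unshifted fragment.
    Fragments matching neither shift, or an empty site set, make the result
    inconclusive — with a per-fragment report either way.
    """
    if not fragments:
        raise BiotransformError("no fragment observations given")
    labels = [f.label for f in fragments]
    if len(set(labels)) != len(labels):
        raise BiotransformError("fragment labels must be unique")
    tol = Tolerance.parse(tolerance)

    shifted, unshifted, unexplained = [], [], []
    for f in fragments:
        window = tol.window_da(f.metabolite_mz)
        if abs(f.shift - delta_m) <= window:
            shifted.append(f)
        elif abs(f.shift) <= window:
            unshifted.append(f)
        else:
            unexplained.append(f)

    per_fragment = "; ".join(
        f"{f.label}: {f.shift:+.4f}" for f in fragments
    )
    if unexplained or not shifted:
        reason = (
            "fragments shifted by neither 0 nor the metabolite shift: "
            + ", ".join(f.label for f in unexplained)
            if unexplained
            else "no shifted fragments"
        )
        return LocalizationResult(
            frozenset(), False,
            [f.label for f in shifted], [f.label for f in unshifted],
            [f.label for f in unexplained],
            f"inconclusive ({reason}); shifts: {per_fragment}",
        )

    common = frozenset.intersection(*(f.tags for f in shifted))
    excluded = frozenset().union(*(f.tags for f in unshifted)) if unshifted else frozenset()
    site = common - excluded
    if not site:
        return LocalizationResult(
            frozenset(), False,
            [f.label for f in shifted], [f.label for f in unshifted], [],
            "inconclusive (no site class is in every shifted fragment and "
            f"no unshifted one); shifts: {per_fragment}",
        )
    return LocalizationResult(
        site, True,
        [f.label for f in shifted], [f.label for f in unshifted], [],
        f"site {set(site)}: shifted fragments {[f.label for f in shifted]} all "
        f"contain it; unshifted {[f.label for f in unshifted]} exclude the rest; "
        f"shifts: {per_fragment}",
    )
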