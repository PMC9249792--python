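"""Peak annotation for single-cell negative-mode spectra.

Observed peaks are matched against a bundled metabolite/lipid reference table
by comparing each peak m/z with the theoretical m/z of every allowed ion
species of every record, at a relative tolerance (default 5 ppm).  Isobars
are reported, not resolved: a peak may carry several hits, and the reference
table deliberately contains exact isobars (PC(31:2) and PE(34:2) share one
elemental composition).  Intensity filtering uses a limit of detection of
3x the baseline noise.  Cardiolipin acyl compositions are decomposed into
the phosphatidylglycerol pairs that could have condensed to form them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .chem import (
    AcylComposition,
    ElementalFormula,
    IonMode,
    IonSpecies,
    ion_mz,
)

__all__ = [
    "Peak",
    "MetaboliteRecord",
    "AnnotationHit",
    "RedoxRatios",
    "PATHWAY_GROUPS",
    "GLC6P_FRAGMENT_MZ",
    "load_metabolite_db",
    "annotate_peaks",
    "lod_filter",
    "redox_ratios",
    "group_cumulative_intensity",
    "cl_pg_pairs",
    "calibration_fit",
]

PATHWAY_GROUPS = frozenset(
    {"glycolysis", "TCA", "amino_acid", "phospholipid", "CL", "redox", "other"}
)

#: Diagnostic MS/MS fragment m/z of hexose phosphate (static reference values;
#: fragment spectra are not computed by this package).
GLC6P_FRAGMENT_MZ = (138.9797, 168.9902, 199.0008)

_REDOX_PAIRS = {
    "asc_dha": ("ascorbate", "dehydroascorbate"),
    "gsh_gssg": ("glutathione", "glutathione_oxidized"),
}


@dataclass(frozen=True)
class Peak:
    """One centroided spectral peak: m/z in Th, intensity in arbitrary units."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass(frozen=True)
class MetaboliteRecord:
    """A reference entry: name, constituent formula(s), pathway tag, ion modes.

    Cluster entries carry two or more constituent formulas; all others carry
    exactly one.
    """

    name: str
    formulas: tuple[ElementalFormula, ...]
    pathway_group: str
    ion_modes: tuple[IonMode, ...]

    def __post_init__(self) -> None:
        if self.pathway_group not in PATHWAY_GROUPS:
            raise ValueError(
                f"unknown pathway group {self.pathway_group!r}; "
                f"expected one of {sorted(PATHWAY_GROUPS)}"
            )
        if not self.formulas:
            raise ValueError("record needs at least one formula")
        if not self.ion_modes:
            raise ValueError("record needs at least one ion mode")

    def ions(self) -> list[IonSpecies]:
        """All allowed ion species of this record."""
        return [IonSpecies.make(self.formulas, mode) for mode in self.ion_modes]


@dataclass(frozen=True)
class AnnotationHit:
    """A peak matched to one ion species of one record within tolerance."""

    peak: Peak
    record: MetaboliteRecord
    ion: IonSpecies
    ppm_error: float

    @property
    def theoretical_mz(self) -> float:
        return ion_mz(self.ion)


@dataclass(frozen=True)
class RedoxRatios:
    """Reduced/oxidized intensity ratios; None flags a missing denominator."""

    asc_dha: float | None
    gsh_gssg: float | None


def _parse_record(name: str, formula: str, group: str, modes: str) -> MetaboliteRecord:
    formulas = tuple(ElementalFormula.parse(part) for part in formula.split("+"))
    ion_modes = tuple(IonMode(m.strip()) for m in modes.split(","))
    return MetaboliteRecord(name, formulas, group, ion_modes)


def load_metabolite_db(path=None) -> list[MetaboliteRecord]:
    """Load a metabolite reference table (TSV: name, formula, pathway_group,
    ion_modes).  With no path, the bundled table covering the metabolites and
    lipids detected in trichome stalk-cell sap is used."""
    if path is None:
        source = resources.files("picocell.reference_data") / "metabolites.tsv"
        lines = source.read_text().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    header = lines[0].split("\t")
    expected = ["name", "formula", "pathway_group", "ion_modes"]
    if header != expected:
        raise ValueError(f"metabolite table header {header} != {expected}")
    records = []
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"malformed metabolite row: {line!r}")
        records.append(_parse_record(*fields))
    return records


def annotate_peaks(
    peaks: Sequence[Peak],
    db: Sequence[MetaboliteRecord],
    tolerance_ppm: float = 5.0,
) -> list[AnnotationHit]:
    """Match peaks to reference ions within a relative m/z tolerance.

    Every (record, allowed ion mode) pair is tried against every peak; a hit
    is emitted when |observed - theoretical| / theoretical * 1e6 < tolerance.
    All hits are returned sorted by |ppm_error| — isobaric assignments are
    reported side by side, no winner is chosen.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    candidates: list[tuple[MetaboliteRecord, IonSpecies, float]] = []
    for record in db:
        for ion in record.ions():
            candidates.append((record, ion, ion_mz(ion)))
    hits: list[AnnotationHit] = []
    for peak in peaks:
        for record, ion, theoretical in candidates:
            ppm = (peak.mz - theoretical) / theoretical * 1e6
            if abs(ppm) < tolerance_ppm:
                hits.append(AnnotationHit(peak, record, ion, ppm))
    hits.sort(key=lambda h: abs(h.ppm_error))
    return hits


def lod_filter(peaks: Sequence[Peak], baseline_noise: float) -> list[Peak]:
    """Retain peaks at or above the limit of detection, 3x the baseline noise.

    Order is preserved; the boundary is inclusive ("at least 3 times").
    """
    if baseline_noise <= 0:
        raise ValueError("baseline noise must be positive")
    threshold = 3.0 * baseline_noise
    return [p for p in peaks if p.intensity >= threshold]


def _summed_intensity(hits: Iterable[AnnotationHit], name: str) -> float | None:
    seen: set[tuple[float, float]] = set()
    total = 0.0
    found = False
    for hit in hits:
        if hit.record.name == name:
            found = True
            key = (hit.peak.mz, hit.peak.intensity)
            if key not in seen:
                seen.add(key)
                total += hit.peak.intensity
    return total if found else None


def redox_ratios(hits: Sequence[AnnotationHit]) -> RedoxRatios:
    """ASC/DHA and GSH/GSSG intensity ratios from annotated peaks.

    A ratio is None (flagged undefined) when the oxidized form is absent or
    its summed intensity is zero — never infinity.
    """
    values: dict[str, float | None] = {}
    for key, (reduced, oxidized) in _REDOX_PAIRS.items():
        num = _summed_intensity(hits, reduced)
        den = _summed_intensity(hits, oxidized)
        if num is None or den is None or den == 0:
            values[key] = None
        else:
            values[key] = num / den
    return RedoxRatios(asc_dha=values["asc_dha"], gsh_gssg=values["gsh_gssg"])


def group_cumulative_intensity(hits: Sequence[AnnotationHit], group: str) -> float:
    """Summed intensity of peaks annotated to a pathway group.

    A peak carrying several hits within the same group contributes once.
    """
    if group not in PATHWAY_GROUPS:
        raise ValueError(f"unknown pathway group {group!r}")
    seen: set[tuple[float, float]] = set()
    total = 0.0
    for hit in hits:
        if hit.record.pathway_group == group:
            key = (hit.peak.mz, hit.peak.intensity)
            if key not in seen:
                seen.add(key)
                total += hit.peak.intensity
    return total


def cl_pg_pairs(
    cl: AcylComposition, pg_candidates: Sequence[AcylComposition]
) -> list[tuple[AcylComposition, AcylComposition]]:
    """Phosphatidylglycerol pairs whose acyl totals compose a cardiolipin.

    Returns every unordered pair (a:b, c:d) drawn from the candidate list with
    a + c equal to the cardiolipin's acyl carbons and b + d equal to its
    double bonds.  A candidate pairs with itself only if listed twice.
    """
    results: set[tuple[AcylComposition, AcylComposition]] = set()
    n = len(pg_candidates)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pg_candidates[i], pg_candidates[j]
            if (
                a.carbons + b.carbons == cl.carbons
                and a.double_bonds + b.double_bonds == cl.double_bonds
            ):
                results.add((min(a, b), max(a, b)))
    return sorted(results)


def calibration_fit(moles: Sequence[float], intensities: Sequence[float]):
    """Ordinary least squares of signal intensity on amount of standard.

    Returns a RegressionFit (slope, intercept, r_squared); used to check the
    linearity of the amount–signal relationship for calibration standards.
    """
    from .kinetics import linear_regression

    if len(moles) != len(intensities):
        raise ValueError("moles and intensities must have equal length")
    return linear_regression(moles, intensities)
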