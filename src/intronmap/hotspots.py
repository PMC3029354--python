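"""Clade-level intron hot spots and cross-clade sharing.

An insertion site is a hot spot of a clade when it carries at least one
third (configurable) of all that clade's introns in the gene family.  The
comparison is exact rational arithmetic -- ``count / total >= fraction`` is
evaluated as ``count * q >= total * p`` -- so the boundary case of exactly
one third never falls to floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

from .site_projection import InsertionSite, SiteKey, SiteMatrix


@dataclass(frozen=True)
class Thresholds:
    """The three knobs of the analysis, at their study defaults."""

    hotspot_fraction: Fraction = Fraction(1, 3)
    n_shuffles: int = 200
    evalue_cutoff: float = 0.02

    def __post_init__(self) -> None:
        f = Fraction(self.hotspot_fraction)
        if not (0 < f <= 1):
            raise ValueError("hotspot_fraction must be in (0, 1]")
        object.__setattr__(self, "hotspot_fraction", f)
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")


@dataclass(frozen=True)
class HotSpot:
    clade: str
    family: str
    site: InsertionSite
    n_at_site: int
    n_clade_family_introns: int

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.n_at_site, self.n_clade_family_introns)


def detect_hotspots(
    matrix: SiteMatrix, clade: str, thresholds: Thresholds = Thresholds()
) -> list[HotSpot]:
    """Sites carrying >= hotspot_fraction of the clade's introns in this family.

    The denominator is all placed introns of that clade in the family (one
    family, one clade -- never pooled across families or split per species).
    """
    if clade not in set(matrix.clade_of.values()):
        raise ValueError(f"unknown clade {clade!r} for family {matrix.family}")
    total = matrix.clade_total(clade)
    if total == 0:
        return []
    frac = thresholds.hotspot_fraction
    out: list[HotSpot] = []
    for site in matrix.sites:
        n = matrix.count_at(clade, site.key(matrix.site_identity))
        if n >= 1 and n * frac.denominator >= total * frac.numerator:
            out.append(HotSpot(
                clade=clade, family=matrix.family, site=site,
                n_at_site=n, n_clade_family_introns=total,
            ))
    return sorted(out, key=lambda h: (h.site.column, h.site.phase))


def shared_hotspots(a: Sequence[HotSpot], b: Sequence[HotSpot]) -> list[InsertionSite]:
    """Sites that are hot spots in both lists (same family), ascending column."""
    families = {h.family for h in a} | {h.family for h in b}
    if len(families) > 1:
        raise ValueError(f"hot-spot lists mix families: {sorted(families)}")
    keys_b = {(h.site.column, h.site.phase) for h in b}
    shared = [h.site for h in a if (h.site.column, h.site.phase) in keys_b]
    return sorted(shared, key=lambda s: (s.column, s.phase))


def hotspot_vs_other_clade(
    hotspots: Sequence[HotSpot], matrix: SiteMatrix, other_clade: str
) -> dict[SiteKey, bool]:
    """For each hot spot, does the other clade have any intron at that site?

    The other clade's occupancy need not itself be a hot spot.
    """
    out: dict[SiteKey, bool] = {}
    for h in hotspots:
        if h.family != matrix.family:
            raise ValueError("hot spot and matrix families differ")
        key = h.site.key(matrix.site_identity)
        out[key] = matrix.occupied_by(other_clade, key)
    return out


def write_hotspots_tsv(
    hotspots_by_clade: Mapping[str, Sequence[HotSpot]],
    matrices: Mapping[str, SiteMatrix],
    path: str | Path,
    seed: int | None = None,
) -> None:
    """One row per (clade, family, site) hot spot, with cross-clade occupancy flags."""
    clades = sorted(hotspots_by_clade)
    lines = []
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.append("clade\tfamily\tcolumn\tphase\tn_at_site\tn_clade_family_introns\t"
                 "fraction\t" + "\t".join(f"occupied_in_{c}" for c in clades))
    for clade in clades:
        for h in sorted(hotspots_by_clade[clade],
                        key=lambda h: (h.family, h.site.column, h.site.phase)):
            matrix = matrices[h.family]
            key = h.site.key(matrix.site_identity)
            flags = []
            for other in clades:
                if other == clade:
                    flags.append("-")
                else:
                    flags.append(str(int(matrix.occupied_by(other, key))))
            lines.append("\t".join(map(str, (
                clade, h.family, h.site.column, h.site.phase, h.n_at_site,
                h.n_clade_family_introns,
                f"{h.fraction.numerator}/{h.fraction.denominator}",
            ))) + "\t" + "\t".join(flags))
    Path(path).write_text("\n".join(lines) + "\n")
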