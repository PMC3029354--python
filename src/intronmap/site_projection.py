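"""Project intron anchor residues onto protein multiple-alignment columns.

Two introns from different species (or paralogs) occupy the same insertion
site when their anchor residues land in the same alignment column.  The
per-family presence table built here (genes x sites, cells holding intron
ids) is the substrate for hot-spot detection and pair classification.

Site identity defaults to the alignment column alone; intron phase is
recorded on every site and can optionally be made part of the identity
(``site_identity="column+phase"``) for a stricter definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .gene_models import GeneModel, Intron

log = logging.getLogger("intronmap.site_projection")

GAP_CHARS = "-."

#: a site key is (column,) or (column, phase) depending on identity mode
SiteKey = tuple[int, ...]


@dataclass(frozen=True)
class InsertionSite:
    """An intron position in protein-alignment coordinates (1-based column)."""

    family: str
    column: int
    phase: int

    def key(self, identity: str = "column") -> SiteKey:
        if identity == "column":
            return (self.column,)
        if identity == "column+phase":
            return (self.column, self.phase)
        raise ValueError(f"unknown site identity {identity!r}")


@dataclass
class AlignedFamily:
    """A protein multiple alignment of one gene family (consumed, not computed)."""

    family: str
    rows: list[tuple[str, str]]
    n_columns: int = 0

    def __post_init__(self) -> None:
        if self.rows:
            lengths = {len(s) for _, s in self.rows}
            if len(lengths) != 1:
                raise ValueError(f"{self.family}: alignment rows differ in length")
            self.n_columns = lengths.pop()

    @classmethod
    def from_fasta(cls, path: str | Path, family: str) -> "AlignedFamily":
        rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(family=family, rows=rows)

    def row(self, gene_id: str) -> str:
        for gid, seq in self.rows:
            if gid == gene_id:
                return seq
        raise KeyError(f"{self.family}: gene {gene_id} not in alignment")

    def validate_against(self, genes: Iterable[GeneModel]) -> None:
        """Hard error if any row degaps to something other than the gene's protein."""
        by_id = {gid: seq for gid, seq in self.rows}
        for g in genes:
            if g.gene_id not in by_id:
                continue
            degapped = degap(by_id[g.gene_id])
            if degapped != g.protein_seq:
                raise ValueError(
                    f"{self.family}: alignment row for {g.gene_id} does not match "
                    f"its protein sequence"
                )


def degap(gapped: str) -> str:
    return "".join(c for c in gapped if c not in GAP_CHARS)


@dataclass(frozen=True)
class ColumnMap:
    """Bidirectional residue-index <-> alignment-column mapping for one row.

    ``residue_to_column[i]`` is the 1-based column holding 0-based residue i;
    the inverse is defined only on non-gap columns.
    """

    residue_to_column: tuple[int, ...]
    column_to_residue: Mapping[int, int]

    def column_of(self, residue: int) -> int:
        return self.residue_to_column[residue]

    @property
    def n_residues(self) -> int:
        return len(self.residue_to_column)


def build_column_map(gapped_row: str) -> ColumnMap:
    """Map each residue of a gapped row to its alignment column (injective)."""
    res_to_col: list[int] = []
    col_to_res: dict[int, int] = {}
    for col, ch in enumerate(gapped_row, start=1):
        if ch in GAP_CHARS:
            continue
        col_to_res[col] = len(res_to_col)
        res_to_col.append(col)
    return ColumnMap(tuple(res_to_col), col_to_res)


def project_intron(intron: Intron, colmap: ColumnMap) -> InsertionSite:
    """Place an intron's anchor residue in alignment coordinates.

    The anchor must lie strictly inside the degapped row; an anchor beyond it
    means the alignment and the gene disagree.
    """
    if intron.anchor_residue >= colmap.n_residues:
        raise ValueError(
            f"intron {intron.intron_id}: anchor residue {intron.anchor_residue} "
            f"outside degapped row of length {colmap.n_residues}"
        )
    return InsertionSite(
        family=intron.family,
        column=colmap.column_of(intron.anchor_residue),
        phase=intron.phase,
    )


@dataclass
class SiteMatrix:
    """Per-family genes x insertion-sites presence table.

    ``cells`` maps (gene_id, site key) to the intron ids observed there;
    every projectable intron of the family sits in exactly one cell.
    """

    family: str
    site_identity: str
    sites: list[InsertionSite]
    cells: dict[tuple[str, SiteKey], list[str]]
    gene_order: list[str]
    species_of: dict[str, str]
    clade_of: dict[str, str]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def site_keys(self) -> list[SiteKey]:
        return [s.key(self.site_identity) for s in self.sites]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_introns(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def clade_of_gene(self, gene_id: str) -> str:
        return self.clade_of[gene_id]

    def clade_total(self, clade: str) -> int:
        """Number of placed introns of this family belonging to ``clade``."""
        return sum(
            len(ids) for (gid, _), ids in self.cells.items()
            if self.clade_of[gid] == clade
        )

    def count_at(self, clade: str, key: SiteKey) -> int:
        return sum(
            len(ids) for (gid, k), ids in self.cells.items()
            if k == key and self.clade_of[gid] == clade
        )

    def occupied_by(self, clade: str, key: SiteKey) -> bool:
        return self.count_at(clade, key) > 0

    def site_of_intron(self) -> dict[str, SiteKey]:
        out: dict[str, SiteKey] = {}
        for (_, key), ids in self.cells.items():
            for iid in ids:
                out[iid] = key
        return out

    def restrict_to_clade(self, clade: str) -> "SiteMatrix":
        genes = [g for g in self.gene_order if self.clade_of[g] == clade]
        keep = set(genes)
        cells = {(g, k): v for (g, k), v in self.cells.items() if g in keep}
        observed = {k for (_, k) in cells}
        sites = [s for s in self.sites if s.key(self.site_identity) in observed]
        return SiteMatrix(
            family=self.family, site_identity=self.site_identity, sites=sites,
            cells=cells, gene_order=genes,
            species_of={g: self.species_of[g] for g in genes},
            clade_of={g: clade for g in genes},
        )


def build_site_matrix(
    introns: Sequence[Intron],
    alignment: AlignedFamily,
    clades: Mapping[str, str],
    *,
    site_identity: str = "column",
    strict: bool = True,
) -> SiteMatrix:
    """Project a family's introns and assemble the presence table.

    Introns anchored at the stop codon (anchor == protein length) are
    excluded with a warning; genes missing from the alignment or anchors
    beyond the row are hard errors in strict mode, collected otherwise.
    Sites are ordered by ascending column, then phase.
    """
    colmaps = {gid: build_column_map(seq) for gid, seq in alignment.rows}
    cells: dict[tuple[str, SiteKey], list[str]] = {}
    seen: dict[SiteKey, InsertionSite] = {}
    skipped: list[tuple[str, str]] = []
    gene_ids = [gid for gid, _ in alignment.rows]
    for intron in sorted(introns, key=lambda i: i.intron_id):
        if intron.family != alignment.family:
            raise ValueError(
                f"intron {intron.intron_id} of family {intron.family} fed to "
                f"{alignment.family} matrix"
            )
        try:
            colmap = colmaps[intron.gene_id]
        except KeyError:
            msg = f"gene {intron.gene_id} not present in {alignment.family} alignment"
            if strict:
                raise ValueError(msg) from None
            skipped.append((intron.intron_id, msg))
            continue
        if intron.anchor_residue == colmap.n_residues:
            log.warning(
                "intron %s anchors at the stop codon; excluded from projection",
                intron.intron_id,
            )
            skipped.append((intron.intron_id, "anchor at stop codon"))
            continue
        try:
            site = project_intron(intron, colmap)
        except ValueError as exc:
            if strict:
                raise
            skipped.append((intron.intron_id, str(exc)))
            continue
        key = site.key(site_identity)
        if key not in seen or (site.column, site.phase) < (seen[key].column, seen[key].phase):
            seen[key] = site
        cells.setdefault((intron.gene_id, key), []).append(intron.intron_id)
    sites = sorted(seen.values(), key=lambda s: (s.column, s.phase))
    species_of, clade_of = {}, {}
    for gid in gene_ids:
        sp = _species_of_gene(gid, introns)
        species_of[gid] = sp
    # genes without introns still need species/clade: fall back to clade table keys
    for gid in gene_ids:
        sp = species_of[gid]
        if sp is not None and sp in clades:
            clade_of[gid] = clades[sp]
    missing = [gid for gid in gene_ids if gid not in clade_of]
    for gid in missing:
        # species unknown from introns alone; try prefix match against the table
        sp = next((s for s in clades if gid.startswith(s)), None)
        if sp is None:
            raise ValueError(f"gene {gid}: species/clade assignment unresolved")
        species_of[gid] = sp
        clade_of[gid] = clades[sp]
    return SiteMatrix(
        family=alignment.family, site_identity=site_identity, sites=sites,
        cells=cells, gene_order=gene_ids, species_of=species_of,
        clade_of=clade_of, skipped=skipped,
    )


def _species_of_gene(gene_id: str, introns: Sequence[Intron]) -> str | None:
    for i in introns:
        if i.gene_id == gene_id:
            return i.species
    return None


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_site_matrix_tsv(matrix: SiteMatrix, path: str | Path,
                          seed: int | None = None) -> None:
    """Genes as rows, insertion sites as columns, cells list intron id:length."""
    lines = []
    if seed is not None:
        lines.append(f"# seed: {seed}")
    header = ["gene_id", "species", "clade"] + [
        f"col{s.column}" + (f".p{s.phase}" if matrix.site_identity == "column+phase" else "")
        for s in matrix.sites
    ]
    lines.append("\t".join(header))
    keys = matrix.site_keys
    for gid in matrix.gene_order:
        row = [gid, matrix.species_of[gid], matrix.clade_of[gid]]
        for key in keys:
            ids = matrix.cells.get((gid, key), [])
            row.append(",".join(ids) if ids else ".")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotated_alignment(
    matrix: SiteMatrix, alignment: AlignedFamily, path: str | Path,
    width: int = 60,
) -> None:
    """Alignment text with an 'I'-marker first row flagging insertion-site columns."""
    marker = [" "] * alignment.n_columns
    for s in matrix.sites:
        marker[s.column - 1] = "I"
    marker_row = "".join(marker)
    label_w = max([len("sites")] + [len(gid) for gid, _ in alignment.rows]) + 2
    blocks = []
    for start in range(0, alignment.n_columns, width):
        chunk = [f"{'sites':<{label_w}}{marker_row[start:start + width]}"]
        for gid, seq in alignment.rows:
            chunk.append(f"{gid:<{label_w}}{seq[start:start + width]}")
        blocks.append("\n".join(chunk))
    Path(path).write_text("\n\n".join(blocks) + "\n")
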