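"""Read gene annotations, reconstruct coding structure, extract spliceosomal introns.

Coordinates are GFF3 1-based inclusive on disk and 0-based half-open in
memory; every position printed in a report is 1-based.  A gene's exons are
held 5'->3' in coding orientation, so minus-strand genes appear reverse
complemented throughout.

The quantity that drives all downstream comparison is an intron's
``cds_offset`` -- the number of coding nucleotides strictly upstream of the
insertion point.  Phase and anchor residue follow from it::

    phase          = cds_offset mod 3
    anchor_residue = floor(cds_offset / 3)      (0-based)

so a phase-0 intron anchors to the residue that follows it and a phase-1/2
intron to the residue whose codon it interrupts.  Each intron therefore owns
exactly one residue, hence one column of the protein multiple alignment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

log = logging.getLogger("intronmap.gene_models")

HISTONE_FAMILIES = ("H2A", "H2B", "H3", "H4")

#: longest alternatives first so "H2A" is never read as "H2" + "A"
_FAMILY_RE = re.compile(r"(H2A|H2B|H3|H4)")

_CODONS = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One gene copy of a family, in coding orientation.

    ``exons`` are genomic 0-based half-open intervals ordered 5'->3' in
    coding orientation (descending genomic position on the minus strand).
    ``protein_seq`` never includes the terminal stop; ``has_stop`` records
    whether the CDS ended in one.
    """

    gene_id: str
    species: str
    family: str
    copy_label: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_seq: str
    protein_seq: str
    has_stop: bool

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        total = sum(e - s for s, e in self.exons)
        if total != len(self.cds_seq):
            raise ValueError(f"{self.gene_id}: exon lengths do not sum to CDS length")
        if len(self.cds_seq) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        expect = len(self.cds_seq) // 3 - (1 if self.has_stop else 0)
        if len(self.protein_seq) != expect:
            raise ValueError(f"{self.gene_id}: protein length inconsistent with CDS")

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def protein_length(self) -> int:
        return len(self.protein_seq)


@dataclass(frozen=True)
class Intron:
    """A CDS-interrupting intron, in coding orientation.

    ``genomic_start``/``genomic_end`` are 0-based half-open on the contig
    (ascending regardless of strand); ``seq`` is already reverse complemented
    for minus-strand genes.
    """

    intron_id: str
    gene_id: str
    species: str
    family: str
    ordinal: int
    genomic_start: int
    genomic_end: int
    length_nt: int
    cds_offset: int
    phase: int
    anchor_residue: int
    seq: str

    def __post_init__(self) -> None:
        if self.length_nt != len(self.seq):
            raise ValueError(f"{self.intron_id}: length_nt != len(seq)")
        if self.phase != self.cds_offset % 3:
            raise ValueError(f"{self.intron_id}: phase != cds_offset mod 3")
        if self.anchor_residue != self.cds_offset // 3:
            raise ValueError(f"{self.intron_id}: anchor != floor(cds_offset/3)")
        if self.ordinal < 1:
            raise ValueError(f"{self.intron_id}: ordinal must be >= 1")


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    The terminal stop codon is dropped; an internal stop is a hard error; a
    codon containing anything outside ACGT translates to 'X'.
    """
    protein, _ = _translate(cds)
    return protein


def _translate(cds: str) -> tuple[str, bool]:
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    cds = cds.upper()
    n_codons = len(cds) // 3
    aas: list[str] = []
    has_stop = False
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in _STOPS:
            if i == n_codons - 1:
                has_stop = True
                break
            raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
        aas.append(_CODONS.get(codon, "X"))
    return "".join(aas), has_stop


# ---------------------------------------------------------------------------
# reading annotations
# ---------------------------------------------------------------------------

FamilyMap = Mapping[str, str] | Callable[[str], str | None] | None


def _resolve_family(gene_id: str, name: str | None, family_map: FamilyMap) -> str | None:
    if isinstance(family_map, Mapping):
        return family_map.get(gene_id)
    if callable(family_map):
        return family_map(gene_id)
    for text in (gene_id, name or ""):
        m = _FAMILY_RE.search(text)
        if m:
            return m.group(1)
    return None


def read_family_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (gene_id, family); '#' lines are comments."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene_id, family = line.split("\t")[:2]
        out[gene_id] = family
    return out


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a {record id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_models(
    gff_path: str | Path,
    fasta_path: str | Path,
    family_map: FamilyMap = None,
) -> list[GeneModel]:
    """Build GeneModels from a GFF3 + FASTA pair.

    Coding structure derives from CDS features (exon features are ignored).
    Genes whose CDS length is not a multiple of 3, that contain an internal
    stop, or whose family cannot be resolved are excluded with a warning.
    A CDS referencing a missing or too-short sequence region is a hard error.
    copy_label (e.g. "H2A_2") numbers copies within species+family by
    ascending genomic position, ties broken by contig name; it is cosmetic.
    """
    seqs = read_sequences(fasta_path)
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    raw: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = gene.id
        cds = sorted(
            db.children(gene, featuretype="CDS"), key=lambda f: (f.start, f.end)
        )
        if not cds:
            log.warning("gene %s has no CDS features; skipped", gene_id)
            continue
        contig = gene.seqid
        if contig not in seqs:
            raise ValueError(f"gene {gene_id}: sequence region {contig!r} missing from FASTA")
        contig_seq = seqs[contig]
        strand = gene.strand if gene.strand in "+-" else "+"
        exons_asc = [(f.start - 1, f.end) for f in cds]  # to 0-based half-open
        for (s1, e1), (s2, e2) in zip(exons_asc, exons_asc[1:]):
            if s2 < e1:
                raise ValueError(f"gene {gene_id}: overlapping CDS intervals")
        if exons_asc[-1][1] > len(contig_seq):
            raise ValueError(
                f"gene {gene_id}: CDS extends past end of sequence region {contig!r}"
            )
        cds_seq = "".join(contig_seq[s:e] for s, e in exons_asc)
        exons = tuple(exons_asc)
        if strand == "-":
            cds_seq = reverse_complement(cds_seq)
            exons = tuple(reversed(exons_asc))
        if len(cds_seq) % 3:
            log.warning("gene %s: CDS length %d not divisible by 3; excluded",
                        gene_id, len(cds_seq))
            continue
        try:
            protein, has_stop = _translate(cds_seq)
        except ValueError as exc:
            log.warning("gene %s: %s; excluded", gene_id, exc)
            continue
        name = gene.attributes.get("Name", [None])[0]
        family = _resolve_family(gene_id, name, family_map)
        if family is None:
            log.warning("gene %s: family unresolvable; excluded", gene_id)
            continue
        species = gene.attributes.get("species", [contig])[0]
        raw.append(GeneModel(
            gene_id=gene_id, species=species, family=family, copy_label="",
            contig=contig, strand=strand, exons=exons, cds_seq=cds_seq,
            protein_seq=protein, has_stop=has_stop,
        ))
    return _assign_copy_labels(raw)


def _assign_copy_labels(genes: Sequence[GeneModel]) -> list[GeneModel]:
    by_group: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_group.setdefault((g.species, g.family), []).append(g)
    labelled: dict[str, str] = {}
    for (_, family), members in by_group.items():
        members.sort(key=lambda g: (min(s for s, _ in g.exons), g.contig, g.gene_id))
        for i, g in enumerate(members, start=1):
            labelled[g.gene_id] = f"{family}_{i}"
    return [
        GeneModel(**{**g.__dict__, "copy_label": labelled[g.gene_id]})
        for g in genes
    ]


# ---------------------------------------------------------------------------
# intron extraction
# ---------------------------------------------------------------------------

def extract_introns(gene: GeneModel, contig_seq: str) -> list[Intron]:
    """Extract the CDS-interrupting introns of one gene, 5'->3' in coding order.

    Only gaps between consecutive coding exons are introns (UTR introns are
    invisible here by construction).  Overlapping exons are a hard error;
    non-canonical boundaries (not GT..AG) are accepted with a warning.
    """
    introns: list[Intron] = []
    cds_offset = 0
    ordinal = 0
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        cds_offset += e1 - s1
        if gene.strand == "+":
            lo, hi = e1, s2
        else:
            lo, hi = e2, s1
        if hi < lo:
            raise ValueError(f"gene {gene.gene_id}: overlapping exons (negative intron)")
        if hi == lo:
            log.warning("gene %s: zero-length gap between CDS parts; no intron", gene.gene_id)
            continue
        seq = contig_seq[lo:hi].upper()
        if gene.strand == "-":
            seq = reverse_complement(seq)
        ordinal += 1
        if not (seq[:2] == "GT" and seq[-2:] == "AG"):
            log.warning("intron %s.i%d: non-canonical boundaries %s..%s",
                        gene.gene_id, ordinal, seq[:2], seq[-2:])
        introns.append(Intron(
            intron_id=f"{gene.gene_id}.i{ordinal}",
            gene_id=gene.gene_id, species=gene.species, family=gene.family,
            ordinal=ordinal, genomic_start=lo, genomic_end=hi,
            length_nt=hi - lo, cds_offset=cds_offset,
            phase=cds_offset % 3, anchor_residue=cds_offset // 3, seq=seq,
        ))
    return introns


def extract_all_introns(
    genes: Iterable[GeneModel], seqs: Mapping[str, str]
) -> list[Intron]:
    """Extract introns for every gene; ``seqs`` maps contig id to sequence."""
    out: list[Intron] = []
    for g in genes:
        out.extend(extract_introns(g, seqs[g.contig]))
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_genes_tsv(
    genes: Sequence[GeneModel], introns: Sequence[Intron], path: str | Path,
    seed: int | None = None,
) -> None:
    """One row per gene: the per-species gene/intron count report."""
    n_introns = {g.gene_id: 0 for g in genes}
    for i in introns:
        n_introns[i.gene_id] += 1
    lines = []
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.append("species\tfamily\tcopy_label\tgene_id\tcontig\tstrand\t"
                 "n_exons\tn_introns\tcds_len\tprotein_len\thas_stop")
    for g in sorted(genes, key=lambda g: (g.species, g.family, g.copy_label, g.gene_id)):
        lines.append("\t".join(map(str, (
            g.species, g.family, g.copy_label, g.gene_id, g.contig, g.strand,
            len(g.exons), n_introns[g.gene_id], len(g.cds_seq),
            g.protein_length, int(g.has_stop),
        ))))
    Path(path).write_text("\n".join(lines) + "\n")


_FASTA_KV = ("gene_id", "species", "family", "ordinal", "phase", "cds_offset",
             "anchor_residue", "genomic_start", "genomic_end")


def write_introns_fasta(introns: Sequence[Intron], path: str | Path) -> None:
    """Write intron sequences; headers carry the full intron record."""
    with open(path, "w") as fh:
        for i in sorted(introns, key=lambda x: x.intron_id):
            kv = " ".join(f"{k}={getattr(i, k)}" for k in _FASTA_KV)
            fh.write(f">{i.intron_id} {kv}\n{i.seq}\n")


def read_introns_fasta(path: str | Path) -> list[Intron]:
    """Inverse of :func:`write_introns_fasta`."""
    out: list[Intron] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kv = dict(item.split("=", 1) for item in rec.description.split()[1:])
        seq = str(rec.seq).upper()
        out.append(Intron(
            intron_id=rec.id, gene_id=kv["gene_id"], species=kv["species"],
            family=kv["family"], ordinal=int(kv["ordinal"]),
            genomic_start=int(kv["genomic_start"]), genomic_end=int(kv["genomic_end"]),
            length_nt=len(seq), cds_offset=int(kv["cds_offset"]),
            phase=int(kv["phase"]), anchor_residue=int(kv["anchor_residue"]), seq=seq,
        ))
    return out
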