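"""Synthetic desk-scale datasets with planted, fully known structure.

The generator emulates the statistical shape of a multi-clade, multi-family
intron survey: a handful of clades of species; four gene families with a
variable number of paralogs per species; dominant ("hot-spot") insertion
sites planted per clade and family, some shared across the intron-bearing
clades; rare private single-gene sites; homologous intron sequences derived
from one ancestral sequence per (family, site, clade) and diverged by point
substitution; canonical GT..AG boundaries; intron lengths log-normal within
[20, 250] nt.  Protein evolution is substitution-only, so the true multiple
alignment is gap-free and emitted directly.

Everything planted is returned in a :class:`SyntheticTruth`, which makes
every downstream stage testable against ground truth without any external
data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

from .gene_models import GeneModel, Intron, HISTONE_FAMILIES

log = logging.getLogger("intronmap.synthetic")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"

FUNGAL_CLADES = ("Taphrinomycotina", "Saccharomycotina", "Pezizomycotina",
                 "Basidiomycota")
DEFAULT_INTRON_BEARING = ("Pezizomycotina", "Basidiomycota")

_CODONS_OF: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_OF.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_OF:
    _CODONS_OF[_aa].sort()
_STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntronLengthModel:
    """Log-normal intron lengths, clipped to a plausible spliceosomal range."""

    log_mean: float = 4.3
    log_sd: float = 0.5
    min_nt: int = 20
    max_nt: int = 250


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mimic the shape of a 24-genome fungal histone survey: four
    clades of six species, two of the clades intron-bearing, four families
    with 1-4 paralogs per species, two dominant sites per bearing clade and
    family of which one is shared across the bearing clades, occupancy 0.85,
    a rare private site per gene, and moderate sequence divergence.
    """

    n_clades: int = 4
    species_per_clade: int = 6
    families: tuple[str, ...] = HISTONE_FAMILIES
    clade_names: tuple[str, ...] | None = None
    intron_bearing_clades: tuple[str, ...] | None = None
    paralogs_per_species_family: tuple[int, int] = (1, 4)
    protein_length: tuple[int, int] = (100, 140)
    n_sites_per_clade_family: int = 2
    cross_clade_shared_sites: int = 1
    site_occupancy: float = 0.85
    private_site_rate: float = 0.08
    intron_length: IntronLengthModel = IntronLengthModel()
    protein_divergence_between: float = 0.10
    protein_divergence_within: float = 0.03
    intron_divergence: float = 0.08
    hotspot_fraction: Fraction = Fraction(1, 3)
    seed: int = 0

    def clades(self) -> tuple[str, ...]:
        if self.clade_names is not None:
            return self.clade_names
        if self.n_clades == len(FUNGAL_CLADES):
            return FUNGAL_CLADES
        return tuple(f"Clade{i + 1}" for i in range(self.n_clades))

    def bearing_clades(self) -> tuple[str, ...]:
        if self.intron_bearing_clades is not None:
            return self.intron_bearing_clades
        clades = self.clades()
        if set(DEFAULT_INTRON_BEARING) <= set(clades):
            return DEFAULT_INTRON_BEARING
        return clades

    def validate(self) -> None:
        if self.n_clades < 2:
            raise ValueError("n_clades must be >= 2")
        if len(self.clades()) != self.n_clades:
            raise ValueError("clade_names length must equal n_clades")
        if not set(self.bearing_clades()) <= set(self.clades()):
            raise ValueError("intron_bearing_clades must be a subset of the clades")
        for name, p in (("site_occupancy", self.site_occupancy),
                        ("private_site_rate", self.private_site_rate),
                        ("protein_divergence_between", self.protein_divergence_between),
                        ("protein_divergence_within", self.protein_divergence_within),
                        ("intron_divergence", self.intron_divergence)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.paralogs_per_species_family
        if not (1 <= lo <= hi):
            raise ValueError("paralogs_per_species_family range is empty")
        lo, hi = self.protein_length
        if not (10 <= lo <= hi):
            raise ValueError("protein_length range is empty or too short")
        if self.cross_clade_shared_sites > self.n_sites_per_clade_family:
            raise ValueError("cross_clade_shared_sites exceeds sites per clade")
        if self.n_sites_per_clade_family > 0:
            if self.site_occupancy == 0:
                raise ValueError("site_occupancy 0 with planted sites: hot spots impossible")
            expected = self.site_occupancy / (
                self.n_sites_per_clade_family * self.site_occupancy
                + self.private_site_rate
            )
            if Fraction(expected).limit_denominator(10**9) < self.hotspot_fraction:
                raise ValueError(
                    "config makes planted hot spots arithmetically implausible: "
                    f"expected site fraction {expected:.3f} < "
                    f"{float(self.hotspot_fraction):.3f}"
                )


def survey_scale_config(seed: int = 0) -> SimConfig:
    """The default study conditions: 4 clades x 6 species, 4 families."""
    return SimConfig(seed=seed)


def small_config(seed: int = 0) -> SimConfig:
    """A miniature configuration for fast end-to-end checks."""
    return SimConfig(
        n_clades=2, species_per_clade=3, families=("H2A", "H4"),
        clade_names=("CladeA", "CladeB"), intron_bearing_clades=("CladeA", "CladeB"),
        paralogs_per_species_family=(1, 2), protein_length=(60, 80), seed=seed,
    )


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthSite:
    """One realized insertion site: (family, column) with its carriers."""

    family: str
    clade: str
    column: int
    phase: int
    kind: str  # "shared", "clade" or "private"
    carrier_intron_ids: tuple[str, ...]


@dataclass
class SyntheticTruth:
    config: SimConfig
    clade_of_species: dict[str, str]
    genes: list[GeneModel]
    introns: list[Intron]
    site_rows: list[TruthSite]
    homologous_pairs: list[tuple[str, str]]
    alignments: dict[str, list[tuple[str, str]]]

    def intron_by_id(self) -> dict[str, Intron]:
        return {i.intron_id: i for i in self.introns}

    def distinct_site_columns(self, family: str) -> list[int]:
        return sorted({r.column for r in self.site_rows if r.family == family})

    def clade_family_counts(self, clade: str, family: str) -> dict[int, int]:
        """Realized intron count per column for one clade and family."""
        counts: dict[int, int] = {}
        for r in self.site_rows:
            if r.family == family and r.clade == clade:
                counts[r.column] = counts.get(r.column, 0) + len(r.carrier_intron_ids)
        return counts

    def expected_hotspots(
        self, fraction: Fraction = Fraction(1, 3)
    ) -> dict[tuple[str, str], list[int]]:
        """Hot-spot columns per (clade, family) from realized truth counts."""
        out: dict[tuple[str, str], list[int]] = {}
        clades = sorted(set(self.clade_of_species.values()))
        for clade in clades:
            for family in self.config.families:
                counts = self.clade_family_counts(clade, family)
                total = sum(counts.values())
                if total == 0:
                    continue
                cols = [
                    c for c, n in counts.items()
                    if n * fraction.denominator >= total * fraction.numerator
                ]
                if cols:
                    out[(clade, family)] = sorted(cols)
        return out

    def expected_shared_hotspots(
        self, fraction: Fraction = Fraction(1, 3)
    ) -> dict[tuple[str, str, str], list[int]]:
        """Columns that are hot spots in both clades of each clade pair."""
        hs = self.expected_hotspots(fraction)
        out: dict[tuple[str, str, str], list[int]] = {}
        clades = sorted({c for c, _ in hs})
        for ca, cb in itertools.combinations(clades, 2):
            for family in self.config.families:
                shared = sorted(
                    set(hs.get((ca, family), [])) & set(hs.get((cb, family), []))
                )
                if shared:
                    out[(ca, cb, family)] = shared
        return out


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def mutate_sequence(
    seq: str, per_site_probability: float, alphabet: str,
    rng: np.random.Generator,
) -> str:
    """I.i.d. per-position substitution to a uniformly chosen other symbol."""
    if not 0 <= per_site_probability <= 1:
        raise ValueError("per_site_probability must be in [0, 1]")
    if per_site_probability == 0 or not seq:
        return seq
    hits = rng.random(len(seq)) < per_site_probability
    if not hits.any():
        return seq
    chars = list(seq)
    others = {c: [a for a in alphabet if a != c] for c in set(seq)}
    for i in np.flatnonzero(hits):
        pool = others[chars[i]]
        chars[i] = pool[rng.integers(len(pool))]
    return "".join(chars)


def _random_seq(length: int, alphabet: str, rng: np.random.Generator) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


def _random_intron(length: int, rng: np.random.Generator) -> str:
    return "GT" + _random_seq(length - 4, DNA, rng) + "AG"


def _derived_intron(ancestral: str, divergence: float, rng: np.random.Generator) -> str:
    interior = mutate_sequence(ancestral[2:-2], divergence, DNA, rng)
    return "GT" + interior + "AG"


def _intron_length(model: IntronLengthModel, rng: np.random.Generator) -> int:
    n = int(round(rng.lognormal(model.log_mean, model.log_sd)))
    return max(model.min_nt, min(model.max_nt, n))


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_CODONS_OF[aa][rng.integers(len(_CODONS_OF[aa]))] for aa in protein]
    codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _PlantedSite:
    family: str
    clade: str
    column: int  # 1-based alignment column == residue index + 1 (gap-free)
    phase: int
    kind: str
    ancestral_seq: str


def _plant_sites(cfg: SimConfig, lengths: Mapping[str, int],
                 rng: np.random.Generator) -> tuple[list[_PlantedSite], dict[str, set[int]]]:
    bearing = cfg.bearing_clades()
    planted: list[_PlantedSite] = []
    used: dict[str, set[int]] = {f: set() for f in cfg.families}
    for family in cfg.families:
        n_own = cfg.n_sites_per_clade_family - cfg.cross_clade_shared_sites
        n_cols = cfg.cross_clade_shared_sites + n_own * len(bearing)
        pool = np.arange(2, lengths[family])  # anchors strictly inside the protein
        cols = rng.choice(pool, size=n_cols, replace=False)
        idx = 0
        for _ in range(cfg.cross_clade_shared_sites):
            col, phase = int(cols[idx]), int(rng.integers(3)); idx += 1
            used[family].add(col)
            for clade in bearing:
                planted.append(_PlantedSite(
                    family, clade, col, phase, "shared",
                    _random_intron(_intron_length(cfg.intron_length, rng), rng),
                ))
        for clade in bearing:
            for _ in range(n_own):
                col, phase = int(cols[idx]), int(rng.integers(3)); idx += 1
                used[family].add(col)
                planted.append(_PlantedSite(
                    family, clade, col, phase, "clade",
                    _random_intron(_intron_length(cfg.intron_length, rng), rng),
                ))
    return planted, used


def simulate_dataset(
    cfg: SimConfig, outdir: str | Path | None = None
) -> tuple[SyntheticTruth, dict[str, Path]]:
    """Generate one dataset; optionally write its files under ``outdir``.

    Returns the truth object and (when ``outdir`` is given) the paths of the
    written GFF3, genome FASTA, per-family aligned FASTA, clade table and
    truth tables.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    clades = cfg.clades()
    bearing = set(cfg.bearing_clades())

    species: list[str] = []
    clade_of: dict[str, str] = {}
    for clade in clades:
        for j in range(cfg.species_per_clade):
            name = f"{clade}_sp{j + 1:02d}"
            species.append(name)
            clade_of[name] = clade

    lengths = {
        f: int(rng.integers(cfg.protein_length[0], cfg.protein_length[1] + 1))
        for f in cfg.families
    }
    family_anc = {f: _random_seq(lengths[f], AMINO_ACIDS, rng) for f in cfg.families}
    clade_anc = {
        (f, c): mutate_sequence(family_anc[f], cfg.protein_divergence_between,
                                AMINO_ACIDS, rng)
        for f in cfg.families for c in clades
    }
    planted, used_cols = _plant_sites(cfg, lengths, rng)
    planted_by = {}
    for site in planted:
        planted_by.setdefault((site.family, site.clade), []).append(site)

    genes: list[GeneModel] = []
    introns: list[Intron] = []
    carriers: dict[tuple[str, str, int], list[str]] = {}  # (family, clade, col)
    private_rows: list[TruthSite] = []
    contigs: dict[str, str] = {}
    alignments: dict[str, list[tuple[str, str]]] = {f: [] for f in cfg.families}
    gff_lines = ["##gff-version 3", f"# seed: {cfg.seed}"]

    for sp in species:
        clade = clade_of[sp]
        contig = f"{sp}_contig"
        parts: list[str] = []
        cursor = 0
        for family in cfg.families:
            n_paralogs = int(rng.integers(cfg.paralogs_per_species_family[0],
                                          cfg.paralogs_per_species_family[1] + 1))
            for k in range(1, n_paralogs + 1):
                gene_id = f"{sp}_{family}_{k}"
                protein = mutate_sequence(clade_anc[(family, clade)],
                                          cfg.protein_divergence_within,
                                          AMINO_ACIDS, rng)
                cds = _reverse_translate(protein, rng)
                gene_introns: list[tuple[int, int, int, str, str]] = []
                if clade in bearing:
                    for site in planted_by.get((family, clade), []):
                        if rng.random() < cfg.site_occupancy:
                            seq = _derived_intron(site.ancestral_seq,
                                                  cfg.intron_divergence, rng)
                            gene_introns.append(
                                (3 * (site.column - 1) + site.phase,
                                 site.column, site.phase, seq, site.kind))
                if rng.random() < cfg.private_site_rate:
                    free = sorted(set(range(2, lengths[family])) - used_cols[family])
                    if free:
                        col = int(free[rng.integers(len(free))])
                        used_cols[family].add(col)
                        phase = int(rng.integers(3))
                        seq = _random_intron(_intron_length(cfg.intron_length, rng), rng)
                        gene_introns.append(
                            (3 * (col - 1) + phase, col, phase, seq, "private"))
                gene_introns.sort(key=lambda t: t[0])

                flank = _random_seq(int(rng.integers(80, 151)), DNA, rng)
                parts.append(flank)
                cursor += len(flank)
                gstart = cursor
                strand = "+" if rng.random() < 0.5 else "-"
                oriented, exon_spans, intron_spans = _assemble_gene(cds, gene_introns)
                genomic = oriented if strand == "+" else reverse_complement(oriented)
                parts.append(genomic)
                cursor += len(genomic)
                lg = len(oriented)

                def to_genomic(span: tuple[int, int]) -> tuple[int, int]:
                    s, e = span
                    if strand == "+":
                        return (gstart + s, gstart + e)
                    return (gstart + lg - e, gstart + lg - s)

                exons = tuple(to_genomic(sp_) for sp_ in exon_spans)
                gene = GeneModel(
                    gene_id=gene_id, species=sp, family=family,
                    copy_label=f"{family}_{k}", contig=contig, strand=strand,
                    exons=exons, cds_seq=cds, protein_seq=protein, has_stop=True,
                )
                genes.append(gene)
                alignments[family].append((gene_id, protein))
                cum = 0
                gff_lines.extend(_gff_for_gene(gene, contig, strand))
                for ordinal, ((off, col, phase, seq, kind), span) in enumerate(
                        zip(gene_introns, intron_spans), start=1):
                    gs, ge = to_genomic(span)
                    intron = Intron(
                        intron_id=f"{gene_id}.i{ordinal}", gene_id=gene_id,
                        species=sp, family=family, ordinal=ordinal,
                        genomic_start=gs, genomic_end=ge, length_nt=len(seq),
                        cds_offset=off, phase=off % 3, anchor_residue=off // 3,
                        seq=seq,
                    )
                    introns.append(intron)
                    if kind == "private":
                        private_rows.append(TruthSite(
                            family, clade, col, phase, "private",
                            (intron.intron_id,),
                        ))
                    else:
                        carriers.setdefault((family, clade, col), []).append(
                            intron.intron_id)
        tail = _random_seq(int(rng.integers(80, 151)), DNA, rng)
        parts.append(tail)
        contigs[contig] = "".join(parts)

    site_rows: list[TruthSite] = []
    for site in planted:
        ids = tuple(carriers.get((site.family, site.clade, site.column), []))
        if ids:
            site_rows.append(TruthSite(
                site.family, site.clade, site.column, site.phase, site.kind, ids))
    site_rows.extend(private_rows)
    site_rows.sort(key=lambda r: (r.family, r.column, r.clade))

    homologous: list[tuple[str, str]] = []
    for r in site_rows:
        if r.kind != "private" and len(r.carrier_intron_ids) > 1:
            for a, b in itertools.combinations(sorted(r.carrier_intron_ids), 2):
                homologous.append((a, b))
    homologous.sort()

    truth = SyntheticTruth(
        config=cfg, clade_of_species=clade_of, genes=genes, introns=introns,
        site_rows=site_rows, homologous_pairs=homologous, alignments=alignments,
    )
    paths: dict[str, Path] = {}
    if outdir is not None:
        paths = _write_dataset(truth, contigs, gff_lines, Path(outdir))
    return truth, paths


def _assemble_gene(
    cds: str, gene_introns: Sequence[tuple[int, int, int, str, str]]
) -> tuple[str, list[tuple[int, int]], list[tuple[int, int]]]:
    """Interleave intron sequences into a CDS at the given coding offsets.

    Returns the oriented gene sequence plus exon and intron spans within it
    (0-based half-open, coding orientation).
    """
    oriented: list[str] = []
    exon_spans: list[tuple[int, int]] = []
    intron_spans: list[tuple[int, int]] = []
    pos = 0
    prev = 0
    for off, _col, _phase, seq, _kind in gene_introns:
        exon = cds[prev:off]
        oriented.append(exon)
        exon_spans.append((pos, pos + len(exon)))
        pos += len(exon)
        oriented.append(seq)
        intron_spans.append((pos, pos + len(seq)))
        pos += len(seq)
        prev = off
    exon = cds[prev:]
    oriented.append(exon)
    exon_spans.append((pos, pos + len(exon)))
    return "".join(oriented), exon_spans, intron_spans


def _gff_for_gene(gene: GeneModel, contig: str, strand: str) -> list[str]:
    lo = min(s for s, _ in gene.exons)
    hi = max(e for _, e in gene.exons)
    lines = [
        "\t".join(map(str, (contig, "intronmap_sim", "gene", lo + 1, hi, ".",
                            strand, ".",
                            f"ID={gene.gene_id};Name={gene.gene_id};"
                            f"species={gene.species}"))),
        "\t".join(map(str, (contig, "intronmap_sim", "mRNA", lo + 1, hi, ".",
                            strand, ".",
                            f"ID={gene.gene_id}.t1;Parent={gene.gene_id}"))),
    ]
    cum = 0
    rows = []
    for i, (s, e) in enumerate(gene.exons, start=1):
        frame = (3 - cum % 3) % 3
        cum += e - s
        rows.append((s, e, frame, i))
    for s, e, frame, i in sorted(rows):
        lines.append("\t".join(map(str, (
            contig, "intronmap_sim", "CDS", s + 1, e, ".", strand, frame,
            f"ID={gene.gene_id}.cds{i};Parent={gene.gene_id}.t1"))))
    return lines


def _write_dataset(
    truth: SyntheticTruth, contigs: Mapping[str, str], gff_lines: Sequence[str],
    outdir: Path,
) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    paths: dict[str, Path] = {}

    paths["gff"] = outdir / "annotations.gff3"
    paths["gff"].write_text("\n".join(gff_lines) + "\n")

    paths["fasta"] = outdir / "genome.fasta"
    with open(paths["fasta"], "w") as fh:
        for i, (contig, seq) in enumerate(sorted(contigs.items())):
            desc = f" seed={cfg.seed}" if i == 0 else ""
            fh.write(f">{contig}{desc}\n")
            for j in range(0, len(seq), 80):
                fh.write(seq[j:j + 80] + "\n")

    for family, rows in truth.alignments.items():
        p = outdir / f"alignment_{family}.fasta"
        with open(p, "w") as fh:
            for i, (gid, prot) in enumerate(rows):
                desc = f" seed={cfg.seed}" if i == 0 else ""
                fh.write(f">{gid}{desc}\n{prot}\n")
        paths[f"alignment_{family}"] = p

    paths["clades"] = outdir / "clades.tsv"
    lines = [f"# seed: {cfg.seed}", "species\tclade"]
    lines += [f"{sp}\t{cl}" for sp, cl in sorted(truth.clade_of_species.items())]
    paths["clades"].write_text("\n".join(lines) + "\n")

    paths["truth_sites"] = outdir / "truth_sites.tsv"
    lines = [f"# seed: {cfg.seed}",
             "family\tclade\tcolumn\tphase\tkind\tcarrier_intron_ids"]
    for r in truth.site_rows:
        lines.append("\t".join(map(str, (
            r.family, r.clade, r.column, r.phase, r.kind,
            ",".join(r.carrier_intron_ids)))))
    paths["truth_sites"].write_text("\n".join(lines) + "\n")

    paths["truth_pairs"] = outdir / "truth_pairs.tsv"
    lines = [f"# seed: {cfg.seed}", "intron_a\tintron_b"]
    lines += [f"{a}\t{b}" for a, b in truth.homologous_pairs]
    paths["truth_pairs"].write_text("\n".join(lines) + "\n")
    return paths
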