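"""End-to-end orchestration: extract -> project -> hot spots -> pairs.

Every report the run writes is a plain-text TSV (or annotated alignment
text), and a ``manifest.json`` records the package version, seed,
thresholds, input digests and collected warnings.  With a fixed seed the
whole bundle is byte-identical across runs; no timestamps are written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .gene_models import (
    FamilyMap, GeneModel, Intron, extract_all_introns, read_family_map,
    read_gene_models, read_sequences, write_genes_tsv, write_introns_fasta,
)
from .hotspots import (
    HotSpot, Thresholds, detect_hotspots, hotspot_vs_other_clade,
    shared_hotspots, write_hotspots_tsv,
)
from .similarity import (
    IntronPair, PairSummary, ScoringScheme, find_similar_pairs,
    summarize_pairs, write_pair_summary_tsv, write_pairs_tsv,
)
from .site_projection import (
    AlignedFamily, SiteMatrix, build_site_matrix, write_annotated_alignment,
    write_site_matrix_tsv,
)
from .synthetic import SimConfig, SyntheticTruth, simulate_dataset

log = logging.getLogger("intronmap.pipeline")


def read_clades(path: str | Path) -> dict[str, str]:
    """Read the species -> clade assignment TSV ('#' lines are comments)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if cols[0] == "species":
            continue
        out[cols[0]] = cols[1]
    return out


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one pipeline run.

    Exactly one of (``gff``+``fasta``+``alignment_dir``+``clades``) or
    ``simulate`` must be supplied.
    """

    outdir: str | Path = "intronmap_out"
    gff: str | Path | None = None
    fasta: str | Path | None = None
    alignment_dir: str | Path | None = None
    clades: str | Path | None = None
    simulate: SimConfig | None = None
    family_map: FamilyMap = None
    thresholds: Thresholds = Thresholds()
    scoring: ScoringScheme = ScoringScheme()
    site_identity: str = "column"
    shuffle: str = "mono"
    seed: int = 0
    strict: bool = True
    run_pairs: bool = True

    def validate(self) -> None:
        file_inputs = [self.gff, self.fasta, self.alignment_dir, self.clades]
        if self.simulate is not None:
            if any(p is not None for p in file_inputs):
                raise ValueError("supply either input paths or simulate, not both")
            return
        missing = [name for name, p in zip(
            ("gff", "fasta", "alignment_dir", "clades"), file_inputs) if p is None]
        if missing:
            raise ValueError(f"missing input paths: {', '.join(missing)}")
        for name, p in zip(("gff", "fasta", "alignment_dir", "clades"), file_inputs):
            if not Path(p).exists():
                raise ValueError(f"{name} path does not exist: {p}")


@dataclass
class RunResult:
    """In-memory view of everything a run computed and wrote."""

    outdir: Path
    genes: list[GeneModel]
    introns: list[Intron]
    matrices: dict[str, SiteMatrix]
    hotspots: dict[tuple[str, str], list[HotSpot]]  # (clade, family)
    shared: dict[tuple[str, str, str], list]  # (clade_a, clade_b, family)
    pairs: list[IntronPair]
    summary: PairSummary | None
    truth: SyntheticTruth | None = None
    warnings: list[str] = field(default_factory=list)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full analysis and write the report bundle."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    truth: SyntheticTruth | None = None
    if cfg.simulate is not None:
        truth, paths = simulate_dataset(cfg.simulate, outdir / "simulated")
        gff, fasta, clades_path = paths["gff"], paths["fasta"], paths["clades"]
        alignment_dir = outdir / "simulated"
    else:
        gff, fasta = Path(cfg.gff), Path(cfg.fasta)
        clades_path = Path(cfg.clades)
        alignment_dir = Path(cfg.alignment_dir)

    family_map = cfg.family_map
    if isinstance(family_map, (str, Path)):
        family_map = read_family_map(family_map)

    clades = read_clades(clades_path)
    genes = read_gene_models(gff, fasta, family_map)
    seqs = read_sequences(fasta)
    introns = extract_all_introns(genes, seqs)
    write_genes_tsv(genes, introns, outdir / "genes.tsv", seed=cfg.seed)
    write_introns_fasta(introns, outdir / "introns.fasta")

    families = sorted({g.family for g in genes})
    matrices: dict[str, SiteMatrix] = {}
    site_of: dict[str, tuple[int, ...]] = {}
    for family in families:
        aln_path = alignment_dir / f"alignment_{family}.fasta"
        if not aln_path.exists():
            msg = f"no alignment file for family {family}: {aln_path}"
            if cfg.strict:
                raise FileNotFoundError(msg)
            warnings.append(msg)
            continue
        alignment = AlignedFamily.from_fasta(aln_path, family)
        alignment.validate_against(g for g in genes if g.family == family)
        fam_introns = [i for i in introns if i.family == family]
        matrix = build_site_matrix(
            fam_introns, alignment, clades,
            site_identity=cfg.site_identity, strict=cfg.strict,
        )
        matrices[family] = matrix
        warnings.extend(f"{iid}: {why}" for iid, why in matrix.skipped)
        site_of.update(matrix.site_of_intron())
        write_site_matrix_tsv(matrix, outdir / f"site_matrix_{family}.tsv",
                              seed=cfg.seed)
        write_annotated_alignment(matrix, alignment,
                                  outdir / f"annotated_alignment_{family}.txt")

    clade_names = sorted(set(clades.values()))
    hotspots: dict[tuple[str, str], list[HotSpot]] = {}
    by_clade: dict[str, list[HotSpot]] = {c: [] for c in clade_names}
    for family, matrix in matrices.items():
        present = set(matrix.clade_of.values())
        for clade in clade_names:
            if clade not in present:
                continue
            hs = detect_hotspots(matrix, clade, cfg.thresholds)
            if hs:
                hotspots[(clade, family)] = hs
                by_clade[clade].extend(hs)
    write_hotspots_tsv(by_clade, matrices, outdir / "hotspots.tsv", seed=cfg.seed)

    shared: dict[tuple[str, str, str], list] = {}
    for i, ca in enumerate(clade_names):
        for cb in clade_names[i + 1:]:
            for family in matrices:
                s = shared_hotspots(hotspots.get((ca, family), []),
                                    hotspots.get((cb, family), []))
                if s:
                    shared[(ca, cb, family)] = s
    _write_shared_tsv(shared, outdir / "shared_hotspots.tsv", cfg.seed)

    pairs: list[IntronPair] = []
    summary: PairSummary | None = None
    if cfg.run_pairs:
        pairs = find_similar_pairs(
            introns, site_of, cfg.thresholds, cfg.scoring,
            seed=cfg.seed, shuffle=cfg.shuffle,
        )
        summary = summarize_pairs(pairs)
        write_pairs_tsv(pairs, outdir / "pairs.tsv", seed=cfg.seed)
        write_pair_summary_tsv(summary, outdir / "pair_summary.tsv", seed=cfg.seed)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "site_identity": cfg.site_identity,
        "shuffle": cfg.shuffle,
        "thresholds": {
            "hotspot_fraction": str(cfg.thresholds.hotspot_fraction),
            "n_shuffles": cfg.thresholds.n_shuffles,
            "evalue_cutoff": cfg.thresholds.evalue_cutoff,
        },
        "scoring": {
            "match": cfg.scoring.match, "mismatch": cfg.scoring.mismatch,
            "gap_open": cfg.scoring.gap_open, "gap_extend": cfg.scoring.gap_extend,
        },
        "inputs": {
            "gff": _sha256(Path(gff)), "fasta": _sha256(Path(fasta)),
            "clades": _sha256(Path(clades_path)),
        },
        "counts": {
            "genes": len(genes),
            "introns": len(introns),
            "introns_per_family": {
                f: sum(1 for i in introns if i.family == f) for f in families
            },
            "sites_per_family": {f: m.n_sites for f, m in matrices.items()},
            "hotspots": sum(len(v) for v in hotspots.values()),
            "significant_pairs": len(pairs),
        },
        "warnings": warnings,
        "notes": ["no multiple-testing correction is applied across intron pairs"],
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return RunResult(
        outdir=outdir, genes=genes, introns=introns, matrices=matrices,
        hotspots=hotspots, shared=shared, pairs=pairs, summary=summary,
        truth=truth, warnings=warnings,
    )


def _write_shared_tsv(shared: Mapping[tuple[str, str, str], Sequence],
                      path: Path, seed: int) -> None:
    lines = [f"# seed: {seed}", "clade_a\tclade_b\tfamily\tcolumn\tphase"]
    for (ca, cb, family), sites in sorted(shared.items()):
        for s in sites:
            lines.append(f"{ca}\t{cb}\t{family}\t{s.column}\t{s.phase}")
    path.write_text("\n".join(lines) + "\n")
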