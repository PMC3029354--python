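"""Sequence-similar intron pairs: local alignment + shuffle significance.

Every unordered pair of introns is scored with Smith-Waterman local
alignment under affine gap costs (DNA defaults: match +5, mismatch -4,
gap open -16 including the first gapped position, gap extend -4).  The
observed score is then compared against the scores of the same alignment
run on ``n_shuffles`` random permutations of the shorter sequence; a
Gumbel (extreme-value) distribution is fitted to the shuffled scores by
maximum likelihood and the pair's E-value is the expected number of
shuffled comparisons reaching the observed score,

    E = n_shuffles * P_gumbel(S >= observed).

The empirical tail probability (r+1)/(n+1) is always reported alongside
and replaces the E-value when the shuffled score distribution is
degenerate (zero spread).  Pairs below the E-value cutoff are classified
by family and insertion site.  The shorter sequence of each pair is the
one shuffled, which reduces the variance of the null.

No multiple-testing correction is applied across pairs; reports carry a
note to that effect.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .gene_models import Intron
from .hotspots import Thresholds
from .site_projection import SiteKey

log = logging.getLogger("intronmap.similarity")

CATEGORIES = ("same_site_same_gene", "diff_site_same_gene", "diff_gene")

_EULER_GAMMA = 0.5772156649015329

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGTN"):
    _ENCODE[ord(_c)] = _i


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap DNA scoring; gap_open includes the first gapped position."""

    match: int = 5
    mismatch: int = -4
    gap_open: int = -16
    gap_extend: int = -4

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")


@dataclass(frozen=True)
class SimilarityResult:
    score: int
    evalue: float
    empirical_p: float
    n_shuffles: int
    seed: int

    def __post_init__(self) -> None:
        if not (0 < self.empirical_p <= 1):
            raise ValueError("empirical_p must be in (0, 1]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class IntronPair:
    """A significant pair; intron_a < intron_b lexicographically."""

    intron_a: str
    intron_b: str
    species_a: str
    species_b: str
    family_a: str
    family_b: str
    result: SimilarityResult
    category: str

    @property
    def same_species(self) -> bool:
        return self.species_a == self.species_b

    @property
    def species_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.species_a, self.species_b)))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Smith-Waterman kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_kernel(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, -(1 << 40), dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        diag = 0
        F = -(1 << 40)
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = match if (ai == b[j - 1] and ai < 4) else mismatch
            h = diag + sub
            e = E[j] + gap_extend
            eo = H[j] + gap_open
            if eo > e:
                e = eo
            E[j] = e
            f = F + gap_extend
            fo = H[j - 1] + gap_open
            if fo > f:
                f = fo
            F = f
            diag = H[j]
            v = h
            if e > v:
                v = e
            if f > v:
                v = f
            if v < 0:
                v = 0
            H[j] = v
            if v > best:
                best = v
    return best


@njit(cache=True)
def _shuffled_scores(a, b, n_shuffles, window, match, mismatch, gap_open,
                     gap_extend, seed):  # pragma: no cover
    """Scores of a vs n random shufflings of b (Fisher-Yates per window).

    window == 0 means whole-sequence (mononucleotide) shuffling; window k > 0
    permutes within consecutive blocks of length k.
    """
    np.random.seed(seed)
    out = np.empty(n_shuffles, dtype=np.int64)
    bb = b.copy()
    m = bb.shape[0]
    w = m if window == 0 else window
    for k in range(n_shuffles):
        for start in range(0, m, w):
            end = min(start + w, m)
            for i in range(end - 1, start, -1):
                j = start + np.random.randint(0, i - start + 1)
                t = bb[i]
                bb[i] = bb[j]
                bb[j] = t
        out[k] = _sw_kernel(bb, a, match, mismatch, gap_open, gap_extend)
    return out


def _encode(seq: str, name: str = "sequence") -> np.ndarray:
    if not seq:
        raise ValueError(f"empty {name}")
    arr = _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq.upper()) - set("ACGTN"))
        raise ValueError(f"{name} contains non-ACGTN symbols: {bad}")
    return arr


def smith_waterman(a: str, b: str, scheme: ScoringScheme = ScoringScheme()) -> int:
    """Maximal local-alignment score of two DNA sequences (N scores as mismatch).

    Score 0 means the empty alignment is optimal.
    """
    return int(_sw_kernel(
        _encode(a, "sequence a"), _encode(b, "sequence b"),
        scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend,
    ))


# ---------------------------------------------------------------------------
# Gumbel fit and shuffle significance
# ---------------------------------------------------------------------------

def _gumbel_mle(scores: np.ndarray) -> tuple[float, float] | None:
    """Maximum-likelihood (mu, beta) of a Gumbel max-value distribution.

    Solves the profile-likelihood equation for beta by bracketed root
    finding; returns None for a degenerate (zero-spread) sample.
    """
    x = scores.astype(np.float64)
    sd = x.std()
    if sd == 0.0:
        return None
    xbar = x.mean()
    z = x - x.min()  # location shift leaves beta's equation unchanged

    def eqn(beta: float) -> float:
        w = np.exp(-z / beta)
        return beta - xbar + float((x * w).sum() / w.sum())

    beta0 = sd * math.sqrt(6.0) / math.pi
    lo, hi = beta0 / 8.0, beta0 * 8.0
    try:
        flo, fhi = eqn(lo), eqn(hi)
        for _ in range(6):
            if flo * fhi <= 0:
                break
            lo /= 4.0
            hi *= 4.0
            flo, fhi = eqn(lo), eqn(hi)
        if flo * fhi > 0:
            raise ValueError("no bracket")
        beta = float(brentq(eqn, lo, hi, xtol=1e-9, rtol=1e-12))
    except (ValueError, OverflowError):
        # fall back to the method-of-moments estimate
        beta = beta0
    w = np.exp(-z / beta)
    mu = float(x.min() - beta * math.log(w.mean()))
    return mu, beta


def _gumbel_sf(x: float, mu: float, beta: float) -> float:
    """P(S >= x) under Gumbel(mu, beta); stable in the far right tail."""
    z = (x - mu) / beta
    if z < -700:
        return 1.0
    return -math.expm1(-math.exp(-z))


def _significance(
    a_arr: np.ndarray, b_arr: np.ndarray, scheme: ScoringScheme,
    n_shuffles: int, seed: int, window: int,
) -> SimilarityResult:
    if b_arr.shape[0] > a_arr.shape[0]:  # shuffle the shorter sequence
        a_arr, b_arr = b_arr, a_arr
    observed = int(_sw_kernel(
        a_arr, b_arr, scheme.match, scheme.mismatch, scheme.gap_open,
        scheme.gap_extend,
    ))
    shuffled = _shuffled_scores(
        a_arr, b_arr, n_shuffles, window, scheme.match, scheme.mismatch,
        scheme.gap_open, scheme.gap_extend, seed,
    )
    r = int((shuffled >= observed).sum())
    empirical_p = (r + 1) / (n_shuffles + 1)
    fit = _gumbel_mle(shuffled)
    if fit is None:
        evalue = empirical_p
    else:
        mu, beta = fit
        evalue = n_shuffles * _gumbel_sf(float(observed), mu, beta)
    return SimilarityResult(
        score=observed, evalue=float(evalue), empirical_p=empirical_p,
        n_shuffles=n_shuffles, seed=seed,
    )


def _parse_shuffle(shuffle: str) -> int:
    if shuffle == "mono":
        return 0
    if shuffle.startswith("window:"):
        k = int(shuffle.split(":", 1)[1])
        if k < 2:
            raise ValueError("window size must be >= 2")
        return k
    raise ValueError(f"unknown shuffle mode {shuffle!r}")


def shuffle_significance(
    a: str, b: str, scheme: ScoringScheme = ScoringScheme(),
    n_shuffles: int = 200, seed: int = 0, shuffle: str = "mono",
) -> SimilarityResult:
    """Score a against b and against ``n_shuffles`` permutations of the shorter.

    ``shuffle`` is "mono" (uniform whole-sequence permutation) or
    "window:<k>" (permutation within consecutive k-nt blocks).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    return _significance(
        _encode(a, "sequence a"), _encode(b, "sequence b"),
        scheme, n_shuffles, seed, _parse_shuffle(shuffle),
    )


# ---------------------------------------------------------------------------
# all-pairs search and classification
# ---------------------------------------------------------------------------

def _pair_seed(master_seed: int, id_a: str, id_b: str) -> int:
    digest = hashlib.sha256(f"{master_seed}|{id_a}|{id_b}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31 - 1) + 1


def _categorize(fam_a: str, fam_b: str, key_a: SiteKey, key_b: SiteKey) -> str:
    if fam_a != fam_b:
        return "diff_gene"
    if key_a == key_b:
        return "same_site_same_gene"
    return "diff_site_same_gene"


def find_similar_pairs(
    introns: Sequence[Intron],
    site_of: Mapping[str, SiteKey],
    thresholds: Thresholds = Thresholds(),
    scheme: ScoringScheme = ScoringScheme(),
    seed: int = 0,
    shuffle: str = "mono",
) -> list[IntronPair]:
    """Shuffle-test every unordered intron pair; keep E < cutoff, classified.

    Per-pair seeds derive deterministically from the master seed and the
    sorted intron-id pair, so results are independent of input order.  Pairs
    involving an intron absent from ``site_of`` (unprojectable anchor) are
    excluded from classification with a warning.
    """
    window = _parse_shuffle(shuffle)
    ordered = sorted(introns, key=lambda i: i.intron_id)
    arrays = {i.intron_id: _encode(i.seq, i.intron_id) for i in ordered}
    pairs: list[IntronPair] = []
    n_unprojectable = 0
    for ia in range(len(ordered)):
        a = ordered[ia]
        for ib in range(ia + 1, len(ordered)):
            b = ordered[ib]
            pseed = _pair_seed(seed, a.intron_id, b.intron_id)
            res = _significance(
                arrays[a.intron_id], arrays[b.intron_id], scheme,
                thresholds.n_shuffles, pseed, window,
            )
            if res.evalue >= thresholds.evalue_cutoff:
                continue
            if a.intron_id not in site_of or b.intron_id not in site_of:
                n_unprojectable += 1
                log.warning(
                    "pair (%s, %s) significant but unclassifiable "
                    "(unprojectable intron); excluded", a.intron_id, b.intron_id,
                )
                continue
            pairs.append(IntronPair(
                intron_a=a.intron_id, intron_b=b.intron_id,
                species_a=a.species, species_b=b.species,
                family_a=a.family, family_b=b.family,
                result=res,
                category=_categorize(
                    a.family, b.family,
                    site_of[a.intron_id], site_of[b.intron_id],
                ),
            ))
    if n_unprojectable:
        log.warning("%d significant pairs excluded as unclassifiable", n_unprojectable)
    return pairs


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def format_percentage(pct: float) -> str:
    """Display rounding: integer percent at >= 10, one decimal below."""
    return f"{pct:.0f}%" if pct >= 10 else f"{pct:.1f}%"


@dataclass(frozen=True)
class PairSummary:
    n_pairs: int
    counts: Mapping[str, int]
    species_pair_counts: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_pairs:
            raise ValueError("category counts must sum to n_pairs")

    def percentage(self, category: str) -> float:
        if self.n_pairs == 0:
            return 0.0
        return 100.0 * self.counts.get(category, 0) / self.n_pairs

    def species_pair_percentage(self, pair: tuple[str, str]) -> float:
        if self.n_pairs == 0:
            return 0.0
        key = tuple(sorted(pair))
        return 100.0 * self.species_pair_counts.get(key, 0) / self.n_pairs


def summarize_pairs(pairs: Sequence[IntronPair]) -> PairSummary:
    """Category counts/percentages and unordered species-pair tallies.

    Within-species pairs count toward the (species, species) diagonal.
    An empty input yields a valid all-zero summary.
    """
    counts = {c: 0 for c in CATEGORIES}
    sp_counts: dict[tuple[str, str], int] = {}
    for p in pairs:
        counts[p.category] += 1
        sp_counts[p.species_pair] = sp_counts.get(p.species_pair, 0) + 1
    return PairSummary(
        n_pairs=len(pairs), counts=counts,
        species_pair_counts=dict(sorted(sp_counts.items())),
    )


def write_pairs_tsv(pairs: Sequence[IntronPair], path: str | Path,
                    seed: int | None = None) -> None:
    lines = []
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.append("# no multiple-testing correction is applied across pairs")
    lines.append("intron_a\tintron_b\tspecies_a\tspecies_b\tfamily_a\tfamily_b\t"
                 "score\tevalue\tempirical_p\tcategory\tsame_species")
    for p in sorted(pairs, key=lambda p: (p.intron_a, p.intron_b)):
        lines.append("\t".join(map(str, (
            p.intron_a, p.intron_b, p.species_a, p.species_b,
            p.family_a, p.family_b, p.result.score,
            f"{p.result.evalue:.6g}", f"{p.result.empirical_p:.6g}",
            p.category, int(p.same_species),
        ))))
    Path(path).write_text("\n".join(lines) + "\n")


def write_pair_summary_tsv(summary: PairSummary, path: str | Path,
                           seed: int | None = None) -> None:
    lines = []
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.append("# no multiple-testing correction is applied across pairs")
    lines.append(f"n_pairs\t{summary.n_pairs}")
    for c in CATEGORIES:
        pct = summary.percentage(c)
        lines.append(f"{c}\t{summary.counts.get(c, 0)}\t{format_percentage(pct)}")
    lines.append("species_a\tspecies_b\tn_pairs\tpercentage")
    ranked = sorted(summary.species_pair_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    for (sa, sb), n in ranked:
        lines.append(f"{sa}\t{sb}\t{n}\t"
                     f"{format_percentage(summary.species_pair_percentage((sa, sb)))}")
    Path(path).write_text("\n".join(lines) + "\n")
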