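"""Descriptive statistics: pairwise diversity, ROH, D and f4-ratio.

All rates are per kbp (or per site) of *callable* genome. Individuals are
single diploid genomes; D and f4 statistics therefore work on one randomly
sampled allele per individual per site (pseudo-haploidisation), with the
sampling stream seeded and documented. Standard errors come from a weighted
block jackknife over contiguous genomic blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import GenotypeMatrix

__all__ = [
    "DiversityResult",
    "ROHSegment",
    "DStatResult",
    "F4RatioResult",
    "pairwise_diff_per_kbp",
    "call_roh",
    "d_statistic",
    "f4_ratio",
    "weighted_block_jackknife",
]

ROH_TIERS_BP = (500_000, 1_000_000, 1_500_000)


# ---------------------------------------------------------------------------
# Pairwise diversity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityResult:
    sample_pair: tuple[str, str]
    diff_per_kbp: float
    n_callable_kbp: float
    rng_seed: int | None


def _sample_alleles(dosages: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """One allele per individual per site: 0/2 are forced, 1 uses ``draws``."""
    return np.where(dosages == 1, draws, dosages // 2).astype(np.int8)


def pairwise_diff_per_kbp(
    geno: GenotypeMatrix, s1: str, s2: str, rng_seed: int = 0
) -> DiversityResult:
    """Proportion of differing sampled genotypes per callable kbp.

    For two distinct individuals one of the two alleles is chosen at random
    per locus (columns of one ``rng.integers(0, 2, (n_sites, 2))`` draw, in
    the order ``(s1, s2)``); for a self comparison the individual's two
    chromosomes are compared, i.e. its heterozygosity per kbp.
    """
    kbp = geno.callable_length / 1000.0
    if kbp == 0:
        raise ValueError("empty callable genome")
    if s1 == s2:
        het = int((geno.dosages[:, geno.sample_index(s1)] == 1).sum())
        return DiversityResult((s1, s2), het / kbp, kbp, None)
    cols = geno.dosages[:, [geno.sample_index(s1), geno.sample_index(s2)]]
    rng = np.random.default_rng(rng_seed)
    draws = rng.integers(0, 2, size=cols.shape)
    alleles = _sample_alleles(cols, draws)
    ndiff = int((alleles[:, 0] != alleles[:, 1]).sum())
    return DiversityResult((s1, s2), ndiff / kbp, kbp, rng_seed)


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROHSegment:
    """A run of homozygosity (0-based half-open genomic coordinates)."""

    contig: str
    start: int
    end: int
    callable_fraction: float
    tier: float  # largest satisfied minimum span, Mbp (0.5 / 1.0 / 1.5)

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_intervals(intervals: np.ndarray) -> np.ndarray:
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if iv.size == 0:
        return iv
    if (iv[:, 1] <= iv[:, 0]).any():
        raise ValueError("intervals must satisfy start < end")
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append(np.array([s, e]))
    return np.array(merged)


def call_roh(
    het_positions: dict[str, np.ndarray],
    callable_mask: dict[str, np.ndarray],
    *,
    window_kbp: float = 1.0,
    expected_het_per_kbp: float = 1.0,
    het_fraction: float = 0.1,
    min_callable_fraction: float = 0.67,
    tiers_bp: tuple[int, ...] = ROH_TIERS_BP,
) -> list[ROHSegment]:
    """Call runs of homozygosity from heterozygous-site positions.

    The callable genome of each contig (mask gaps compressed) is cut into
    consecutive windows of ``window_kbp`` callable kbp. A window is low-het
    iff its heterozygote count is strictly below ``het_fraction`` times the
    expected count (``expected_het_per_kbp`` per callable kbp — with the
    defaults, < 0.1 het per kbp). Maximal runs of low-het windows become
    segments if their physical span exceeds the smallest tier, at least
    ``min_callable_fraction`` of the span is callable, and each segment is
    labelled with the largest tier its span exceeds.
    """
    out: list[ROHSegment] = []
    win = int(round(window_kbp * 1000))
    tiers = sorted(tiers_bp)
    for contig in sorted(callable_mask):
        mask = _merge_intervals(callable_mask[contig])
        if mask.size == 0:
            continue
        lens = mask[:, 1] - mask[:, 0]
        cum = np.concatenate([[0], np.cumsum(lens)])  # callable offsets
        total = int(cum[-1])
        pos = np.asarray(het_positions.get(contig, np.empty(0)), dtype=np.int64)
        if pos.size and (np.diff(pos) < 0).any():
            raise ValueError(f"het positions on {contig} are not sorted")
        # genomic -> callable coordinate for hets inside the mask
        i = np.searchsorted(mask[:, 0], pos, side="right") - 1
        inside = (i >= 0) & (pos < mask[np.clip(i, 0, None), 1])
        cc = cum[i[inside]] + (pos[inside] - mask[i[inside], 0])
        n_windows = -(-total // win)
        counts = np.bincount(cc // win, minlength=n_windows)
        win_callable = np.full(n_windows, win, dtype=np.int64)
        if total % win:
            win_callable[-1] = total % win
        low = counts < het_fraction * expected_het_per_kbp * (win_callable / 1000.0)

        def to_genomic(c: int) -> int:
            j = np.searchsorted(cum, c, side="right") - 1
            return int(mask[j, 0] + (c - cum[j]))

        # maximal runs of low windows
        edges = np.diff(np.concatenate([[0], low.astype(int), [0]]))
        for w0, w1 in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
            c0, c1 = w0 * win, min(w1 * win, total)
            g0 = to_genomic(c0)
            g1 = to_genomic(c1 - 1) + 1
            span = g1 - g0
            if span <= tiers[0]:
                continue
            frac = (c1 - c0) / span
            if frac < min_callable_fraction:
                continue
            tier = max(t for t in tiers if span > t)
            out.append(ROHSegment(contig, g0, g1, frac, tier / 1e6))
    return out


# ---------------------------------------------------------------------------
# Weighted block jackknife
# ---------------------------------------------------------------------------

def weighted_block_jackknife(
    theta_hat: float, theta_minus: np.ndarray, weights: np.ndarray
) -> float:
    """Standard error of a statistic by the weighted block jackknife.

    ``theta_minus[j]`` is the statistic recomputed with block ``j`` deleted
    and ``weights[j]`` the block's information content (its site count).
    Uses the delete-one weighted-jackknife variance with pseudovalues
    ``tau_j = h_j * theta_hat - (h_j - 1) * theta_minus_j`` where
    ``h_j = n / m_j``.
    """
    m = np.asarray(weights, dtype=float)
    theta_minus = np.asarray(theta_minus, dtype=float)
    keep = m > 0
    m, theta_minus = m[keep], theta_minus[keep]
    g = m.size
    if g < 2:
        raise ValueError("need at least two non-empty blocks for a jackknife")
    n = m.sum()
    h = n / m
    theta_j = g * theta_hat - ((1.0 - m / n) * theta_minus).sum()
    tau = h * theta_hat - (h - 1.0) * theta_minus
    var = ((tau - theta_j) ** 2 / (h - 1.0)).sum() / g
    return float(np.sqrt(var))


def _genome_blocks(geno: GenotypeMatrix, block_size: int) -> np.ndarray:
    """Assign each site to a contiguous genomic block (fragments laid end
    to end in id order)."""
    lengths = np.asarray(geno.fragment_lengths, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])[:-1]
    gpos = offsets[geno.fragment_ids] + geno.positions
    return gpos // block_size


# ---------------------------------------------------------------------------
# D statistic (ABBA-BABA)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DStatResult:
    quartet: tuple[str, str, str, str]
    abba: float
    baba: float
    d: float
    se: float
    z: float
    n_blocks: int


def _pseudo_haploid(
    geno: GenotypeMatrix, labels: tuple[str, ...], rng_seed: int
) -> np.ndarray:
    """One sampled allele per individual per site, columns in label order.

    The random draws come from a single ``rng.integers(0, 2,
    (n_sites, len(labels)))`` call with ``default_rng(rng_seed)``, consumed
    column-by-column in the given label order.
    """
    cols = geno.dosages[:, [geno.sample_index(l) for l in labels]]
    rng = np.random.default_rng(rng_seed)
    draws = rng.integers(0, 2, size=cols.shape)
    return _sample_alleles(cols, draws)


def d_statistic(
    geno: GenotypeMatrix,
    w: str,
    x: str,
    y: str,
    outgroup: str,
    *,
    block_size: int = 5_000_000,
    rng_seed: int = 0,
) -> DStatResult:
    """ABBA-BABA test for gene flow, D = (nABBA - nBABA)/(nABBA + nBABA).

    Alleles are recoded relative to the sampled outgroup allele (the
    outgroup defines the ancestral state). ABBA sites: W ancestral, X and Y
    derived; BABA sites: W derived, X ancestral, Y derived. Significance by
    weighted block jackknife over contiguous genomic blocks, Z = D/SE.
    """
    alleles = _pseudo_haploid(geno, (w, x, y, outgroup), rng_seed)
    rel = alleles[:, :3] ^ alleles[:, 3:4]  # derived = differs from outgroup
    abba = (rel[:, 0] == 0) & (rel[:, 1] == 1) & (rel[:, 2] == 1)
    baba = (rel[:, 0] == 1) & (rel[:, 1] == 0) & (rel[:, 2] == 1)
    n_abba, n_baba = int(abba.sum()), int(baba.sum())
    if n_abba + n_baba == 0:
        raise ValueError("no ABBA or BABA informative sites")
    d = (n_abba - n_baba) / (n_abba + n_baba)

    blocks = _genome_blocks(geno, block_size)
    uniq = np.unique(blocks)
    a_b = np.array([abba[blocks == b].sum() for b in uniq], dtype=float)
    b_b = np.array([baba[blocks == b].sum() for b in uniq], dtype=float)
    m = a_b + b_b
    keep = m > 0
    a_b, b_b, m = a_b[keep], b_b[keep], m[keep]
    theta_minus = (n_abba - a_b - (n_baba - b_b)) / (n_abba + n_baba - m)
    se = weighted_block_jackknife(d, theta_minus, m)
    z = d / se if se > 0 else np.sign(d) * np.inf
    return DStatResult((w, x, y, outgroup), n_abba, n_baba, d, se, z, int(m.size))


# ---------------------------------------------------------------------------
# f4 and the f4-ratio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class F4RatioResult:
    numerator: tuple[str, str, str, str]
    denominator: tuple[str, str, str, str]
    alpha: float
    se: float


#: The published ratio forms, as (numerator, denominator) quartet templates;
#: "X" marks the population whose ancestry proportion is being estimated.
F4_RATIO_FORMS = {
    "eurasian_in_hunter_gatherers": (
        ("Han", "Yoruba", "X", "Chimp"),
        ("Han", "Yoruba", "French", "Chimp"),
    ),
    "eurasian_in_africans": (
        ("Sardinian", "Han", "X", "Yoruba"),
        ("Sardinian", "Han", "French", "Yoruba"),
    ),
    "neanderthal_in_africans": (
        ("Denisova", "Chimp", "X", "Yoruba"),
        ("Denisova", "Chimp", "Neanderthal", "Yoruba"),
    ),
}


def _f4_site_products(alleles: np.ndarray) -> np.ndarray:
    a, b, c, d = (alleles[:, i].astype(float) for i in range(4))
    return (a - b) * (c - d)


def f4_ratio(
    geno: GenotypeMatrix,
    numerator: tuple[str, str, str, str],
    denominator: tuple[str, str, str, str],
    *,
    block_size: int = 5_000_000,
    rng_seed: int = 0,
    min_denominator_z: float = 0.0,
) -> F4RatioResult:
    """Admixture proportion as a ratio of two f4 statistics.

    Each f4 is the mean over sites of (a-b)(c-d) on sampled alleles; the
    ratio of the two sums over the shared site set is the estimate, with a
    weighted block jackknife SE of the ratio itself. Populations named in
    both quartets share one allele sampling per site.
    """
    labels = tuple(dict.fromkeys(numerator + denominator))
    alleles = _pseudo_haploid(geno, labels, rng_seed)
    col = {l: i for i, l in enumerate(labels)}
    num = _f4_site_products(alleles[:, [col[l] for l in numerator]])
    den = _f4_site_products(alleles[:, [col[l] for l in denominator]])

    blocks = _genome_blocks(geno, block_size)
    uniq = np.unique(blocks)
    num_b = np.array([num[blocks == b].sum() for b in uniq])
    den_b = np.array([den[blocks == b].sum() for b in uniq])
    m = np.array([(blocks == b).sum() for b in uniq], dtype=float)
    tot_num, tot_den = num.sum(), den.sum()
    if tot_den == 0:
        raise ValueError(f"denominator f4{denominator} is zero")
    if min_denominator_z > 0:
        d_minus = np.where(
            m < m.sum(), (tot_den - den_b) / (m.sum() - m), tot_den / m.sum()
        )
        se_den = weighted_block_jackknife(tot_den / m.sum(), d_minus, m)
        if se_den > 0 and abs(tot_den / m.sum()) / se_den < min_denominator_z:
            raise ValueError(
                f"denominator f4{denominator} not significantly non-zero"
            )
    alpha = tot_num / tot_den
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_minus = (tot_num - num_b) / (tot_den - den_b)
    ok = np.isfinite(theta_minus)
    se = weighted_block_jackknife(alpha, theta_minus[ok], m[ok])
    return F4RatioResult(tuple(numerator), tuple(denominator), float(alpha), se)
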