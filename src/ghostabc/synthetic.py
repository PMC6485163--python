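"""Synthetic fixtures: the stand-in for the real genome panel.

Every generator is seeded, returns (or writes) a manifest with the planted
truth, and emits the same containers and formats the pipeline consumes, so
the whole stack is exercisable without any download. None of the
generators attempt to model sequencing error or mapping bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np

from .dataio import write_bed, write_manifest, write_vcf
from .models import Prior, build_model, default_priors, draw_parameters
from .sfs import JointSFS, compute_jsfs, inject_noise
from .simulate import (
    FragmentSet,
    GenotypeMatrix,
    desk_fragments,
    simulate_demography,
    simulate_fragments,
)

__all__ = [
    "toy_genotype_matrix",
    "make_roh_genome",
    "make_admixed_panel",
    "estimate_planted_pulse",
    "prior_midpoint",
    "noise_spectrum",
    "JsfsBank",
    "make_jsfs_bank",
]


def toy_genotype_matrix(
    dosages: np.ndarray,
    sample_labels: tuple[str, ...],
    *,
    positions: np.ndarray | None = None,
    fragment_ids: np.ndarray | None = None,
    fragment_lengths: tuple[int, ...] = (1_000_000,),
) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from a hand-written dosage table."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n = dosages.shape[0]
    if positions is None:
        positions = np.arange(n, dtype=np.int64) * 100
    if fragment_ids is None:
        fragment_ids = np.zeros(n, dtype=np.int64)
    return GenotypeMatrix(
        fragment_ids=np.asarray(fragment_ids, dtype=np.int64),
        positions=np.asarray(positions, dtype=np.int64),
        dosages=dosages,
        sample_labels=tuple(sample_labels),
        fragment_lengths=fragment_lengths,
    )


# ---------------------------------------------------------------------------
# Planted-ROH genome
# ---------------------------------------------------------------------------

def make_roh_genome(
    out_dir: str | Path,
    *,
    planted_segments: list[tuple[int, int]],
    genome_length: int = 10_000_000,
    background_het_per_kbp: float = 1.0,
    inside_het_per_kbp: float = 0.0,
    mask_gaps: list[tuple[int, int]] | None = None,
    rng_seed: int = 0,
    sample_name: str = "sample1",
) -> dict:
    """Write a single-contig VCF + BED + manifest with planted ROH.

    Heterozygous sites are Poisson-placed at ``background_het_per_kbp``
    outside the planted segments and at ``inside_het_per_kbp`` (default 0,
    and required < 5% of background) inside them. ``mask_gaps`` are cut out
    of the otherwise fully callable contig.
    """
    segs = sorted(planted_segments)
    for (s0, e0), (s1, _) in zip(segs, segs[1:]):
        if s1 < e0:
            raise ValueError("planted segments overlap")
    if inside_het_per_kbp >= 0.05 * background_het_per_kbp and background_het_per_kbp > 0:
        raise ValueError("inside-het rate must stay below 5% of background")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)

    gaps = sorted(mask_gaps or [])
    mask_iv = []
    prev = 0
    for s, e in gaps:
        if s > prev:
            mask_iv.append((prev, s))
        prev = max(prev, e)
    if prev < genome_length:
        mask_iv.append((prev, genome_length))
    mask = {"frag0": np.array(mask_iv or np.empty((0, 2)), dtype=np.int64).reshape(-1, 2)}

    def in_planted(p: np.ndarray) -> np.ndarray:
        hit = np.zeros(p.size, dtype=bool)
        for s, e in segs:
            hit |= (p >= s) & (p < e)
        return hit

    positions: list[int] = []
    n_bg = rng.poisson(background_het_per_kbp * genome_length / 1000.0)
    bg = np.unique(rng.integers(0, genome_length, size=n_bg))
    bg = bg[~in_planted(bg)]
    positions.extend(bg.tolist())
    if inside_het_per_kbp > 0:
        for s, e in segs:
            n_in = rng.poisson(inside_het_per_kbp * (e - s) / 1000.0)
            positions.extend(np.unique(rng.integers(s, e, size=n_in)).tolist())
    pos = np.unique(np.asarray(positions, dtype=np.int64))
    # drop hets falling in mask gaps: they would be invisible in real data
    iv = mask["frag0"]
    if iv.size:
        j = np.searchsorted(iv[:, 0], pos, side="right") - 1
        pos = pos[(j >= 0) & (pos < iv[np.clip(j, 0, None), 1])]
    else:
        pos = pos[:0]

    geno = GenotypeMatrix(
        fragment_ids=np.zeros(pos.size, dtype=np.int64),
        positions=pos,
        dosages=np.ones((pos.size, 1), dtype=np.int8),
        sample_labels=(sample_name,),
        fragment_lengths=(genome_length,),
        callable_mask={0: iv},
    )
    write_vcf(geno, out_dir / "genome.vcf")
    write_bed(mask, out_dir / "mask.bed")
    manifest = {
        "kind": "roh_genome",
        "rng_seed": rng_seed,
        "genome_length": genome_length,
        "planted_segments": segs,
        "background_het_per_kbp": background_het_per_kbp,
        "inside_het_per_kbp": inside_het_per_kbp,
        "mask_gaps": gaps,
        "n_het_sites": int(pos.size),
        "sample_name": sample_name,
    }
    write_manifest(manifest, out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Planted-admixture panel
# ---------------------------------------------------------------------------

#: Panel for admixture fixtures: an outgroup, three Eurasian-like genomes
#: (Sar and Fr sisters, Han outside), and two African-like genomes
#: (Yor and the admixture target X, sisters).
ADMIX_PANEL = ("O", "Sar", "Fr", "Han", "Yor", "X")


def make_admixed_panel(
    alpha: float,
    *,
    fragments: FragmentSet | None = None,
    rng_seed: int = 0,
    t_admix_gen: float = 300.0,
    t_afr_split_gen: float = 3_000.0,
    t_eur_splits_gen: tuple[float, float] = (600.0, 2_500.0),
    t_cross_gen: float = 4_000.0,
    t_outgroup_gen: float = 40_000.0,
    ne: float = 10_000.0,
    ne_shared_eur: float = 2_000.0,
) -> tuple[GenotypeMatrix, dict]:
    """Coalescent panel with one planted admixture pulse of proportion alpha.

    Forward in time, a fraction ``alpha`` of the African-like target ``X``
    is replaced by migrants from the European-like donor ``Fr`` at
    ``t_admix_gen``. With this topology the planted proportion is
    identified by ``f4(Sar, Han; X, Yor) / f4(Sar, Han; Fr, Yor)`` and, for
    ``alpha = 0``, D(Yor, X; Fr, O) is a calibrated null. The shared
    Sardinian-French ancestral branch is bottlenecked (``ne_shared_eur``)
    so the f4 denominator drift is strong and the ratio well conditioned,
    mimicking the pronounced shared European drift that makes the ratio
    usable on real genomes.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if fragments is None:
        fragments = desk_fragments(200, 20_000)
    dem = msprime.Demography()
    for name in ADMIX_PANEL:
        dem.add_population(name=name, initial_size=ne)
    for name in ("AncSF", "AncEur", "AncAfr", "AncHum", "Root"):
        dem.add_population(
            name=name, initial_size=ne_shared_eur if name == "AncSF" else ne
        )
    if alpha > 0:
        dem.add_mass_migration(time=t_admix_gen, source="X", dest="Fr", proportion=alpha)
    dem.add_population_split(time=t_eur_splits_gen[0], derived=["Sar", "Fr"], ancestral="AncSF")
    dem.add_population_split(time=t_eur_splits_gen[1], derived=["AncSF", "Han"], ancestral="AncEur")
    dem.add_population_split(time=t_afr_split_gen, derived=["Yor", "X"], ancestral="AncAfr")
    dem.add_population_split(time=t_cross_gen, derived=["AncEur", "AncAfr"], ancestral="AncHum")
    dem.add_population_split(time=t_outgroup_gen, derived=["AncHum", "O"], ancestral="Root")
    dem.sort_events()

    samples = [msprime.SampleSet(1, population=p, ploidy=2) for p in ADMIX_PANEL]
    geno = simulate_demography(dem, samples, ADMIX_PANEL, fragments, rng_seed)
    manifest = {
        "kind": "admixed_panel",
        "alpha": alpha,
        "rng_seed": rng_seed,
        "t_admix_gen": t_admix_gen,
        "panel": list(ADMIX_PANEL),
        "n_fragments": fragments.n_fragments,
        "total_bp": fragments.total_length,
    }
    return geno, manifest


def estimate_planted_pulse(
    alpha: float,
    n_replicates: int,
    *,
    fragments: FragmentSet | None = None,
    rng_seed: int = 0,
    block_size: int = 250_000,
) -> tuple[float, float]:
    """Simulator calibration harness: recover a planted pulse proportion.

    Simulates ``n_replicates`` admixed panels with a single pulse of
    proportion ``alpha`` and estimates it by the f4-ratio. Returns the mean
    estimate and its Monte-Carlo standard error; the mean should bracket
    ``alpha`` within a few SE.
    """
    from .stats import f4_ratio

    if fragments is None:
        fragments = desk_fragments(200, 20_000)
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(1, 2**31 - 1, size=n_replicates)
    estimates = []
    for s in seeds:
        geno, _ = make_admixed_panel(alpha, fragments=fragments, rng_seed=int(s))
        res = f4_ratio(
            geno,
            ("Sar", "Han", "X", "Yor"),
            ("Sar", "Han", "Fr", "Yor"),
            block_size=block_size,
            rng_seed=int(s),
        )
        estimates.append(res.alpha)
    est = np.asarray(estimates)
    se = est.std(ddof=1) / np.sqrt(n_replicates) if n_replicates > 1 else np.inf
    return float(est.mean()), float(se)


# ---------------------------------------------------------------------------
# jSFS banks
# ---------------------------------------------------------------------------

def prior_midpoint(priors: dict[str, Prior]) -> dict[str, float]:
    """Midpoint of every prior (geometric midpoint for log-uniforms)."""
    out = {}
    for name, p in priors.items():
        if p.family == "log-uniform":
            out[name] = math.sqrt(p.low * p.high)
        else:
            out[name] = 0.5 * (p.low + p.high)
    return out


def noise_spectrum(
    fragments: FragmentSet, rng_seed: int, model_id: str = "A"
) -> JointSFS:
    """The designated noise panel's jSFS.

    Stands in for the observed spectrum of the real noise-panel genomes: a
    single simulation of the baseline model at its prior midpoints, under a
    seed kept separate from training and pseudo-observed seeds.
    """
    params = prior_midpoint(default_priors(model_id))
    model = build_model(model_id, params)
    geno = simulate_fragments(model, fragments, rng_seed)
    return compute_jsfs(geno)


@dataclass
class JsfsBank:
    """Labelled, noise-injected jSFS vectors with full provenance."""

    X: np.ndarray  # rows: flattened normalised spectra
    labels: np.ndarray  # generating model id per row
    params: list[dict[str, float]]
    provenance: list[str] = field(default_factory=list)
    partitions: dict[str, np.ndarray] = field(default_factory=dict)

    def rows(self, partition: str) -> np.ndarray:
        return self.partitions[partition]

    def param_column(self, name: str) -> np.ndarray:
        return np.array([p.get(name, np.nan) for p in self.params])


def simulate_jsfs(
    model_id: str,
    params: dict[str, float],
    fragments: FragmentSet,
    rng_seed: int,
) -> JointSFS:
    """One simulation: resolve the model, simulate fragments, tally the jSFS."""
    model = build_model(model_id, params)
    geno = simulate_fragments(model, fragments, rng_seed)
    return compute_jsfs(geno)


def make_jsfs_bank(
    model_ids: tuple[str, ...],
    n_per_model: int,
    fragments: FragmentSet,
    rng_seed: int,
    *,
    priors: dict[str, dict[str, Prior]] | None = None,
    noise: JointSFS | None = None,
    lam: float = 0.5,
    partition_counts: dict[str, int] | None = None,
) -> JsfsBank:
    """Simulate a labelled bank of noise-injected, normalised jSFS vectors.

    Each row draws fresh parameters from the model's priors, simulates the
    fragment set, tallies the jSFS, blends in the noise spectrum and
    normalises. ``partition_counts`` (e.g. ``{"train": 80, "reference": 80,
    "pseudo": 20}`` summing to ``n_per_model``) assigns disjoint
    provenance-tracked partitions within each model's rows.
    """
    if priors is None:
        priors = {m: default_priors(m) for m in model_ids}
    if partition_counts is not None and sum(partition_counts.values()) != n_per_model:
        raise ValueError("partition counts must sum to n_per_model")
    if noise is None:
        noise = noise_spectrum(fragments, rng_seed=981_427_003)
    rng = np.random.default_rng(rng_seed)
    X, labels, params_list, prov = [], [], [], []
    part_rows: dict[str, list[int]] = {k: [] for k in (partition_counts or {})}
    row = 0
    for m in model_ids:
        seeds = rng.integers(1, 2**31 - 1, size=(n_per_model, 3))
        boundaries: list[tuple[str, int]] = []
        if partition_counts:
            start = 0
            for part, cnt in partition_counts.items():
                boundaries.append((part, start + cnt))
                start += cnt
        for i in range(n_per_model):
            draw = draw_parameters(priors[m], m, int(seeds[i, 0]))
            sim = simulate_jsfs(m, draw, fragments, int(seeds[i, 1]))
            noisy = inject_noise(sim, noise, lam=lam, rng_seed=int(seeds[i, 2]))
            X.append(noisy.normalize().flatten())
            labels.append(m)
            params_list.append(draw)
            prov.append(f"{m}:{i}:{seeds[i, 1]}")
            if partition_counts:
                for part, upto in boundaries:
                    if i < upto:
                        part_rows[part].append(row)
                        break
            row += 1
    return JsfsBank(
        X=np.vstack(X),
        labels=np.array(labels),
        params=params_list,
        provenance=prov,
        partitions={k: np.array(v, dtype=int) for k, v in part_rows.items()},
    )
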