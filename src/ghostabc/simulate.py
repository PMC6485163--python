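"""Fragmented coalescent simulation of the seven-genome panel.

The callable genome is modelled as a set of independent fragments; within a
fragment recombination acts at a uniform rate, between fragments linkage is
broken entirely. Each fragment is an independent coalescent replicate under
the resolved :class:`~ghostabc.models.DemographicModel`, simulated with
msprime. Genotypes are diploid derived-allele dosages (0/1/2), polarised by
the simulated ancestral state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .models import PANEL, DemographicModel

__all__ = [
    "FragmentSet",
    "GenotypeMatrix",
    "desk_fragments",
    "full_scale_fragments",
    "to_msprime_demography",
    "simulate_fragments",
]

#: Default rates per bp per generation (configurable on FragmentSet).
DEFAULT_MUTATION_RATE = 1.25e-8
DEFAULT_RECOMBINATION_RATE = 1.0e-8


@dataclass(frozen=True)
class FragmentSet:
    """Lengths and per-bp rates of the simulated callable fragments."""

    lengths: tuple[int, ...]
    mutation_rate: float = DEFAULT_MUTATION_RATE
    recombination_rate: float = DEFAULT_RECOMBINATION_RATE

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lengths):
            raise ValueError("fragment lengths must be > 0")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be >= 0")

    @property
    def n_fragments(self) -> int:
        return len(self.lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))


def equal_fragments(
    n_fragments: int,
    total_length: int,
    *,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    recombination_rate: float = DEFAULT_RECOMBINATION_RATE,
) -> FragmentSet:
    """Split ``total_length`` bp into ``n_fragments`` near-equal fragments.

    The first ``total_length % n_fragments`` fragments get one extra bp so
    the sum is exact.
    """
    base, extra = divmod(total_length, n_fragments)
    lengths = tuple(base + 1 if i < extra else base for i in range(n_fragments))
    return FragmentSet(lengths, mutation_rate, recombination_rate)


def desk_fragments(n_fragments: int = 300, fragment_length: int = 20_000, **kw) -> FragmentSet:
    """Desk-scale preset: 300 fragments of 20 kbp (6 Mbp total)."""
    return FragmentSet((fragment_length,) * n_fragments, **kw)


def full_scale_fragments(**kw) -> FragmentSet:
    """Full-scale preset: 11,642 fragments totalling 393.5 Mbp of callable genome."""
    return equal_fragments(11_642, 393_500_000, **kw)


@dataclass
class GenotypeMatrix:
    """Polarised diploid genotypes at segregating sites across fragments.

    ``dosages[s, k]`` is the derived-allele count (0/1/2) of sample ``k`` at
    site ``s``. Positions are 0-based within their fragment. ``callable_mask``
    maps fragment id -> (n, 2) array of 0-based half-open callable intervals;
    by default every fragment is fully callable.
    """

    fragment_ids: np.ndarray
    positions: np.ndarray
    dosages: np.ndarray
    sample_labels: tuple[str, ...]
    fragment_lengths: tuple[int, ...]
    callable_mask: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.sample_labels):
            raise ValueError("dosages must be n_sites x n_samples")
        if not self.callable_mask:
            self.callable_mask = {
                i: np.array([[0, L]]) for i, L in enumerate(self.fragment_lengths)
            }

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[0]

    @property
    def callable_length(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.callable_mask.values())
        )

    def sample_index(self, label: str) -> int:
        try:
            return self.sample_labels.index(label)
        except ValueError:
            raise KeyError(f"sample {label!r} not in matrix") from None

    def subset_fragments(self, keep: np.ndarray) -> "GenotypeMatrix":
        sel = np.isin(self.fragment_ids, keep)
        return GenotypeMatrix(
            self.fragment_ids[sel],
            self.positions[sel],
            self.dosages[sel],
            self.sample_labels,
            self.fragment_lengths,
            {int(i): self.callable_mask[int(i)] for i in keep},
        )


def to_msprime_demography(model: DemographicModel) -> msprime.Demography:
    """Translate a resolved event list into an msprime Demography.

    Forward-time conventions map to msprime's backward-time ones: a pulse
    ``source -> dest`` of proportion p becomes a mass migration of lineages
    from ``dest`` into ``source``; a continuous forward migration
    donor -> recipient becomes a backward lineage-movement rate from the
    recipient to the donor, switched off (going back) at its onset time.
    """
    dem = msprime.Demography()
    for name, size in model.populations.items():
        dem.add_population(name=name, initial_size=size)

    # Group split events sharing (time, ancestral) into single splits.
    splits: dict[tuple[float, str], list[str]] = {}
    for e in model.events_of("split"):
        splits.setdefault((e.time, e.dest), []).append(e.source)
    for (time, ancestral), derived in splits.items():
        dem.add_population_split(time=time, derived=derived, ancestral=ancestral)

    # Leaf populations that also serve as the ancestral side of a split
    # (e.g. NI splitting from N) must stay active from the present.
    ancestral_only = {e.dest for e in model.events_of("split")} - {
        e.source for e in model.events_of("split")
    }
    for pop in model.populations:
        if pop not in ancestral_only:
            dem[pop].initially_active = True

    for e in model.events_of("pulse_introgression"):
        dem.add_mass_migration(
            time=e.time, source=e.dest, dest=e.source, proportion=e.magnitude
        )

    for e in model.events_of("continuous_migration"):
        donor, recipient = e.source, e.dest
        dem.set_migration_rate(source=recipient, dest=donor, rate=e.magnitude)
        dem.add_migration_rate_change(time=e.time, source=recipient, dest=donor, rate=0.0)

    for e in model.events_of("size_change"):
        dem.add_population_parameters_change(
            time=e.time, population=e.dest, initial_size=e.magnitude
        )

    dem.sort_events()
    return dem


def panel_samples(model: DemographicModel) -> list[msprime.SampleSet]:
    """One diploid sample per panel population, archaics at their ages."""
    out = []
    for pop in PANEL:
        if pop not in model.populations:
            raise ValueError(f"model {model.model_id} lacks panel population {pop!r}")
        out.append(
            msprime.SampleSet(
                1, population=pop, ploidy=2, time=model.sample_ages.get(pop, 0.0)
            )
        )
    return out


def simulate_fragments(
    model: DemographicModel,
    fragments: FragmentSet,
    rng_seed: int,
    *,
    samples: list[msprime.SampleSet] | None = None,
    sample_labels: tuple[str, ...] = PANEL,
) -> GenotypeMatrix:
    """Simulate every fragment independently and stack segregating sites.

    Seeded reproducibly: the ancestry and mutation seeds of each fragment
    are derived from ``rng_seed``. Sites where no sample carries a derived
    allele are dropped. With ``mutation_rate == 0`` the result has zero
    sites.
    """
    if samples is None:
        samples = panel_samples(model)  # validates panel coverage first
    dem = to_msprime_demography(model)
    return simulate_demography(dem, samples, sample_labels, fragments, rng_seed)


def simulate_demography(
    dem: msprime.Demography,
    samples: list[msprime.SampleSet],
    sample_labels: tuple[str, ...],
    fragments: FragmentSet,
    rng_seed: int,
) -> GenotypeMatrix:
    """Fragment-replicate simulation against a raw msprime demography."""
    n_samples = sum(s.num_samples for s in samples)
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(1, 2**31 - 1, size=(fragments.n_fragments, 2))

    frag_ids: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    dosages: list[np.ndarray] = []
    # Group fragments by length so each group runs as msprime replicates.
    lengths = np.asarray(fragments.lengths)
    for L in np.unique(lengths):
        idx = np.flatnonzero(lengths == L)
        reps = msprime.sim_ancestry(
            samples=samples,
            demography=dem,
            sequence_length=int(L),
            recombination_rate=fragments.recombination_rate,
            num_replicates=len(idx),
            random_seed=int(seeds[idx[0], 0]),
        )
        for j, ts in zip(idx, reps):
            if fragments.mutation_rate == 0:
                continue
            mts = msprime.sim_mutations(
                ts,
                rate=fragments.mutation_rate,
                random_seed=int(seeds[j, 1]),
                model=msprime.BinaryMutationModel(),
            )
            if mts.num_sites == 0:
                continue
            gm = mts.genotype_matrix()  # sites x (2*n_diploid), 0=ancestral
            dos = (gm != 0).astype(np.int8).reshape(mts.num_sites, n_samples, 2).sum(2)
            keep = dos.sum(1) > 0
            if not keep.any():
                continue
            site_pos = mts.tables.sites.position[keep].astype(np.int64)
            frag_ids.append(np.full(keep.sum(), j, dtype=np.int64))
            positions.append(site_pos)
            dosages.append(dos[keep].astype(np.int8))

    if frag_ids:
        fid = np.concatenate(frag_ids)
        pos = np.concatenate(positions)
        dos = np.concatenate(dosages)
        order = np.lexsort((pos, fid))
        fid, pos, dos = fid[order], pos[order], dos[order]
    else:
        fid = np.empty(0, dtype=np.int64)
        pos = np.empty(0, dtype=np.int64)
        dos = np.empty((0, n_samples), dtype=np.int8)
    return GenotypeMatrix(
        fragment_ids=fid,
        positions=pos,
        dosages=dos,
        sample_labels=tuple(sample_labels),
        fragment_lengths=tuple(int(l) for l in fragments.lengths),
    )
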