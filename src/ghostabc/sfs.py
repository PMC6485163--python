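"""Multidimensional unfolded joint site frequency spectrum (jSFS).

The jSFS over the seven-genome panel is a 3x3x...x3 (seven axes) tensor of
site counts indexed by the derived-allele dosage (0/1/2) of each diploid
genome, axis order fixed to (N, D, EAs, Eu, WAf, Mbt, Kho). The two
monomorphic corner cells (all dosage 0, all dosage 2) carry no polymorphism
information and are excluded from all tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .models import PANEL
from .simulate import GenotypeMatrix

__all__ = ["JointSFS", "compute_jsfs", "inject_noise"]

log = logging.getLogger(__name__)


@dataclass
class JointSFS:
    """Joint SFS tensor with its axis labels."""

    counts: np.ndarray
    axis_order: tuple[str, ...] = PANEL
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (3,) * len(self.axis_order):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match axis order "
                f"{self.axis_order}"
            )

    @property
    def n_axes(self) -> int:
        return len(self.axis_order)

    @property
    def n_sites(self) -> float:
        return float(self.counts.sum())

    def normalize(self) -> "JointSFS":
        """Return the spectrum scaled to sum to 1 (idempotent)."""
        total = self.counts.sum()
        if total == 0:
            raise ValueError("cannot normalize an empty spectrum (n_sites = 0)")
        return JointSFS(self.counts / total, self.axis_order, normalized=True)

    def flatten(self) -> np.ndarray:
        return self.counts.ravel().copy()

    def reorder(self, axis_order: tuple[str, ...]) -> "JointSFS":
        """Permute axes to a new sample order."""
        perm = [self.axis_order.index(a) for a in axis_order]
        return JointSFS(self.counts.transpose(perm), tuple(axis_order), self.normalized)


def _corner_indices(n_axes: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    return (0,) * n_axes, (2,) * n_axes


def compute_jsfs(
    geno: GenotypeMatrix, axis_order: tuple[str, ...] = PANEL
) -> JointSFS:
    """Tally each polymorphic site into its dosage cell.

    Requires polarised genotypes for every sample in ``axis_order``. Sites
    falling in the monomorphic corners (possible when an input VCF contains
    fixed-derived sites) are excluded.
    """
    cols = [geno.sample_index(a) for a in axis_order]
    dos = geno.dosages[:, cols].astype(np.int64)
    n_axes = len(axis_order)
    if dos.size:
        flat = np.ravel_multi_index(tuple(dos.T), (3,) * n_axes)
        counts = np.bincount(flat, minlength=3**n_axes).astype(float)
        counts = counts.reshape((3,) * n_axes)
    else:
        counts = np.zeros((3,) * n_axes)
    lo, hi = _corner_indices(n_axes)
    dropped = counts[lo] + counts[hi]
    if dropped:
        log.info("compute_jsfs: excluded %d monomorphic-corner sites", int(dropped))
    counts[lo] = 0.0
    counts[hi] = 0.0
    return JointSFS(counts, tuple(axis_order))


def inject_noise(
    sim: JointSFS,
    noise_source: JointSFS,
    lam: float = 0.5,
    n_resample: int | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> JointSFS:
    """Blend a simulated spectrum with an observed noise spectrum.

    The output is a multinomial resample of size ``n_resample`` (default:
    ``sim.n_sites``) from the mixture ``(1-lam) * p_sim + lam * p_noise`` of
    the two normalised spectra. This mirrors noise injection from a
    designated observed-genome panel into every training simulation, so the
    networks learn statistics robust to the observational noise floor.
    """
    if sim.axis_order != noise_source.axis_order:
        raise ValueError(
            f"axis order mismatch: {sim.axis_order} vs {noise_source.axis_order}"
        )
    if not 0.0 <= lam <= 1.0:
        raise ValueError("blend weight lam must be in [0, 1]")
    if n_resample is None:
        n_resample = int(round(sim.n_sites))
    rng = (
        np.random.default_rng(rng_seed)
        if not isinstance(rng_seed, np.random.Generator)
        else rng_seed
    )
    p = (1.0 - lam) * sim.normalize().counts + lam * noise_source.normalize().counts
    flat = p.ravel()
    flat = flat / flat.sum()
    counts = rng.multinomial(n_resample, flat).astype(float).reshape(p.shape)
    return JointSFS(counts, sim.axis_order)
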