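"""Readers and writers for VCF, BED masks and jSFS tables.

Coordinate conventions, stated once and enforced by tests: internal
coordinates are 0-based half-open; VCF is 1-based at the boundary; BED is
native 0-based half-open. Fragments map to VCF contigs named ``frag<i>``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .sfs import JointSFS
from .simulate import GenotypeMatrix

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_bed_mask",
    "write_bed",
    "mask_total_length",
    "write_jsfs_tsv",
    "read_jsfs_tsv",
]

log = logging.getLogger(__name__)


def _contig_name(i: int) -> str:
    return f"frag{i}"


def _contig_index(name: str) -> int:
    if name.startswith("frag"):
        return int(name[4:])
    raise ValueError(f"contig {name!r} does not follow the frag<i> convention")


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF.

    One pseudo-contig per fragment, positions 1-based, ancestral allele in
    INFO/AA. REF is the ancestral allele (A), ALT the derived allele (G);
    genotypes are unphased dosage expansions.
    """
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for i, L in enumerate(geno.fragment_lengths):
            fh.write(f"##contig=<ID={_contig_name(i)},length={L}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_labels)
            + "\n"
        )
        for fid, pos, dos in zip(geno.fragment_ids, geno.positions, geno.dosages):
            cols = [
                _contig_name(int(fid)),
                str(int(pos) + 1),
                ".",
                "A",
                "G",
                ".",
                "PASS",
                "AA=A",
                "GT",
            ] + [gt[int(d)] for d in dos]
            fh.write("\t".join(cols) + "\n")


def read_vcf(
    path: str | Path,
    sample_names: list[str],
    mask: dict[str, np.ndarray] | None = None,
    fragment_lengths: dict[str, int] | None = None,
) -> GenotypeMatrix:
    """Read polarised diploid genotypes for the named samples.

    Positions shift to 0-based internally. Sites are skipped (with logged
    counts) when multi-allelic, outside the mask, or unpolarisable (INFO/AA
    missing or matching neither allele); AA equal to ALT flips dosages.
    """
    vcf = VCF(str(path))
    missing = [s for s in sample_names if s not in vcf.samples]
    if missing:
        raise ValueError(f"samples not in VCF: {missing}")
    cols = [vcf.samples.index(s) for s in sample_names]
    lengths: dict[str, int] = dict(
        zip(vcf.seqnames, vcf.seqlens or [0] * len(vcf.seqnames))
    )
    if fragment_lengths:
        lengths.update(fragment_lengths)
    fids, poss, doss = [], [], []
    n_multi = n_masked = n_unpolarized = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        pos0 = rec.POS - 1
        if mask is not None:
            iv = mask.get(rec.CHROM)
            if iv is None or not (
                (iv[:, 0] <= pos0) & (pos0 < iv[:, 1])
            ).any():
                n_masked += 1
                continue
        aa = rec.INFO.get("AA")
        if aa is None or aa.upper() not in (rec.REF.upper(), rec.ALT[0].upper()):
            n_unpolarized += 1
            continue
        # dosage of the non-ancestral (derived) allele
        alt_dosage = np.array(
            [a + b for a, b, *_ in rec.genotypes], dtype=np.int8
        )[cols]
        dos = alt_dosage if aa.upper() == rec.REF.upper() else 2 - alt_dosage
        fids.append(_contig_index(rec.CHROM))
        poss.append(pos0)
        doss.append(dos)
    log.info(
        "read_vcf: skipped %d multi-allelic, %d masked, %d unpolarized records",
        n_multi, n_masked, n_unpolarized,
    )
    n_frag = (max(fids) + 1) if fids else len(lengths)
    frag_lengths = tuple(
        int(lengths.get(_contig_name(i), 0)) for i in range(n_frag)
    )
    callable_mask = (
        {_contig_index(c): np.asarray(iv) for c, iv in mask.items()}
        if mask is not None
        else {}
    )
    return GenotypeMatrix(
        fragment_ids=np.asarray(fids, dtype=np.int64),
        positions=np.asarray(poss, dtype=np.int64),
        dosages=(
            np.vstack(doss) if doss else np.empty((0, len(sample_names)), np.int8)
        ),
        sample_labels=tuple(sample_names),
        fragment_lengths=frag_lengths,
        callable_mask=callable_mask,
    )


def read_bed_mask(path: str | Path) -> dict[str, np.ndarray]:
    """Read a BED callable mask into merged per-contig interval arrays."""
    from .stats import _merge_intervals

    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            s, e = int(start), int(end)
            if e <= s:
                raise ValueError(f"BED interval with end <= start: {line!r}")
            raw.setdefault(chrom, []).append((s, e))
    return {c: _merge_intervals(np.array(iv)) for c, iv in raw.items()}


def mask_total_length(mask: dict[str, np.ndarray]) -> int:
    return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in mask.values()))


def write_bed(mask: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask):
            for s, e in np.asarray(mask[chrom], dtype=np.int64):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def write_jsfs_tsv(jsfs: JointSFS, path: str | Path) -> None:
    """Flat (cell-index-tuple, count) table; axis order in the header."""
    with open(path, "w") as fh:
        fh.write("# axis_order=" + ",".join(jsfs.axis_order) + "\n")
        fh.write("# normalized=" + str(jsfs.normalized) + "\n")
        fh.write("\t".join(jsfs.axis_order) + "\tcount\n")
        for idx in np.ndindex(jsfs.counts.shape):
            v = float(jsfs.counts[idx])
            if v != 0:
                fh.write("\t".join(map(str, idx)) + f"\t{v!r}\n")


def read_jsfs_tsv(path: str | Path) -> JointSFS:
    axis_order: tuple[str, ...] = ()
    normalized = False
    counts = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# axis_order="):
                axis_order = tuple(line.split("=", 1)[1].split(","))
                counts = np.zeros((3,) * len(axis_order))
            elif line.startswith("# normalized="):
                normalized = line.split("=", 1)[1] == "True"
            elif line and not line.startswith("#") and counts is not None:
                parts = line.split("\t")
                if parts[0] == axis_order[0]:  # column header
                    continue
                idx = tuple(int(x) for x in parts[:-1])
                counts[idx] = float(parts[-1])
    if counts is None:
        raise ValueError(f"{path} has no axis_order header")
    return JointSFS(counts, axis_order, normalized)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
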