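"""Synthetic data generators for every input the pipeline consumes.

Three generators, all pure functions of (configuration, seed):

* multinomially sampled progeny genotype-class counts under the
  killer-protector viability model (emulating scored F2/T1 families);
* Poisson per-base depth profiles for present and absent genes
  (emulating short-read coverage over the S1 region, with a small
  contamination rate modelling cross-mapping noise — no GC or
  mappability bias);
* whole accession panels with lineage-structured haplotypes, written in
  the exact dialects the typing module reads (per-accession VCF and
  depth TSV, a gene BED, and a ground-truth table for accuracy scoring).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .haplotypes import DEFAULT_PANEL, DepthProfile, SnpPanelDef
from .model import KillerProtectorSpec, SporophyteGenotype
from .segregation import ObservedCounts, expected_class_probs

__all__ = [
    "GENE_INTERVALS",
    "LineageSpec",
    "PanelPaths",
    "default_lineages",
    "sample_progeny_counts",
    "simulate_depth_profile",
    "simulate_accession_panel",
]

#: Synthetic S1-g reference layout (BED convention: 0-based half-open).
#: The seven panel sites fall inside the S1TPR interval.
GENE_INTERVALS: dict[str, tuple[str, int, int]] = {
    "S1A4": ("S1_region", 1000, 1900),
    "S1TPR": ("S1_region", 3000, 4200),
    "S1A6": ("S1_region", 5000, 6200),
}

_CONTIG_LENGTH = 8000


def sample_progeny_counts(
    mother: SporophyteGenotype,
    father: SporophyteGenotype,
    spec: KillerProtectorSpec,
    locus: str,
    n: int,
    seed: int,
) -> ObservedCounts:
    """Multinomial draw of *n* progeny from the model's class probabilities."""
    if n < 1:
        raise ValueError("n must be >= 1")
    probs = expected_class_probs(mother, father, spec, locus)
    classes = sorted(probs)
    p = np.array([probs[c] for c in classes], dtype=float)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, p / p.sum())
    return ObservedCounts.from_dict(
        locus, {c: int(d) for c, d in zip(classes, draws) if d > 0}
    )


def simulate_depth_profile(
    gene: str,
    length: int,
    present: bool,
    mean_depth: float,
    seed: int,
    contamination_rate: float = 0.01,
    start: int = 1,
) -> DepthProfile:
    """Independent Poisson per-position depths for a present or absent gene.

    A present gene has rate ``mean_depth`` at every position; an absent
    gene has rate ``mean_depth * contamination_rate`` (stray
    cross-mapping reads).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    lam = mean_depth if present else mean_depth * contamination_rate
    rng = np.random.default_rng(seed)
    depths = rng.poisson(lam, size=length)
    return DepthProfile(gene=gene, start=start, depths=tuple(int(d) for d in depths))


@dataclass(frozen=True)
class LineageSpec:
    """One lineage of a synthetic panel: structure, SNP pattern, size."""

    name: str
    structure: str  # e.g. "A4-TPR-A6" or "TP"
    snp_pattern: str  # 7 states
    n_accessions: int

    def __post_init__(self) -> None:
        if len(self.snp_pattern) != 7:
            raise ValueError("snp_pattern must have 7 states")
        if self.n_accessions < 0:
            raise ValueError("n_accessions must be >= 0")

    @property
    def a4_present(self) -> bool:
        return self.structure.startswith("A4-")

    @property
    def a6_present(self) -> bool:
        return self.structure.endswith("-A6")


def default_lineages(n_glaberrima: int = 10, n_sativa: int = 10) -> list[LineageSpec]:
    """A two-lineage panel emulating the African/Asian rice contrast.

    African-rice-like accessions carry the complete three-gene
    A4-TPR-A6 structure with the all-reference SNP pattern; Asian-rice-
    like accessions carry the one-gene TP structure with derived states
    at sites 1, 3, 4, 6 and the stop-gain site 7.
    """
    refs = "".join(s.ref for s in DEFAULT_PANEL.sites)
    tp_pattern = "".join(
        s.alt if i in (0, 2, 3, 5, 6) else s.ref
        for i, s in enumerate(DEFAULT_PANEL.sites)
    )
    return [
        LineageSpec("glaberrima_like", "A4-TPR-A6", refs, n_glaberrima),
        LineageSpec("sativa_like", "TP", tp_pattern, n_sativa),
    ]


@dataclass(frozen=True)
class PanelPaths:
    """Everything a typing run needs, plus the ground truth."""

    run_dir: Path
    bed: Path
    truth: Path
    accessions: dict[str, dict[str, Path]]  # acc -> {"vcf": ..., "depth": ...}


def _write_bed(path: Path) -> None:
    rows = [
        f"{chrom}\t{start}\t{end}\t{gene}"
        for gene, (chrom, start, end) in GENE_INTERVALS.items()
    ]
    path.write_text("\n".join(rows) + "\n")


def _write_vcf(
    path: Path, accession: str, pattern: str, panel: SnpPanelDef, callable_: bool
) -> None:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={panel.sites[0].chrom},length={_CONTIG_LENGTH}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(accession)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site, state in zip(panel.sites, pattern):
            rec = out.new_record(
                contig=site.chrom, start=site.pos - 1, alleles=(site.ref, site.alt)
            )
            if not callable_ or state == "N":
                gt = (None, None)
            elif state == site.ref:
                gt = (0, 0)
            elif state == site.alt:
                gt = (1, 1)
            else:
                gt = (None, None)
            rec.samples[accession]["GT"] = gt
            out.write(rec)


def simulate_accession_panel(
    lineages: Sequence[LineageSpec],
    out_dir,
    seed: int,
    mean_depth: float = 30.0,
    contamination_rate: float = 0.01,
    panel: SnpPanelDef = DEFAULT_PANEL,
) -> PanelPaths:
    """Write a complete synthetic accession panel under out_dir/run_<seed>.

    Per accession: a 7-site VCF (genotypes per the lineage's SNP
    pattern; missing when mean_depth is 0) and a samtools-depth-style
    TSV over the S1 region genes (Poisson depths; absent genes at the
    contamination rate).  Plus one gene BED and a ground-truth TSV
    (accession, lineage, structure, snp_pattern) for accuracy scoring.
    """
    run_dir = Path(out_dir) / f"run_{seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    bed_path = run_dir / "genes.bed"
    _write_bed(bed_path)
    rng = np.random.default_rng(seed)
    callable_ = mean_depth > 0

    accessions: dict[str, dict[str, Path]] = {}
    truth_rows = []
    for lineage in lineages:
        for i in range(lineage.n_accessions):
            acc = f"{lineage.name}_{i:03d}"
            vcf_path = run_dir / f"{acc}.vcf"
            depth_path = run_dir / f"{acc}.depth.tsv"
            _write_vcf(vcf_path, acc, lineage.snp_pattern, panel, callable_)
            frames = []
            present_by_gene = {
                "S1A4": lineage.a4_present,
                "S1TPR": True,  # every accession carries TPR or TP
                "S1A6": lineage.a6_present,
            }
            for gene, (chrom, start0, end0) in GENE_INTERVALS.items():
                first, last = start0 + 1, end0
                profile = simulate_depth_profile(
                    gene,
                    last - first + 1,
                    present_by_gene[gene],
                    mean_depth,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    contamination_rate=contamination_rate,
                    start=first,
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": np.arange(first, last + 1),
                            "depth": profile.depths,
                        }
                    )
                )
            depth = pd.concat(frames, ignore_index=True)
            depth = depth[depth["depth"] > 0]  # samtools depth omits zero rows
            depth.to_csv(depth_path, sep="\t", index=False, header=False)
            accessions[acc] = {"vcf": vcf_path, "depth": depth_path}
            truth_rows.append(
                {
                    "accession": acc,
                    "lineage": lineage.name,
                    "structure": lineage.structure,
                    "snp_pattern": lineage.snp_pattern,
                }
            )
    truth_path = run_dir / "truth.tsv"
    pd.DataFrame(
        truth_rows, columns=["accession", "lineage", "structure", "snp_pattern"]
    ).to_csv(truth_path, sep="\t", index=False)
    return PanelPaths(
        run_dir=run_dir, bed=bed_path, truth=truth_path, accessions=accessions
    )
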