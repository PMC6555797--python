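"""S1-locus haplotype typing from SNP panels and per-base depth profiles.

The S1TPR/S1TP coding sequences differ at seven single-nucleotide sites
(sites 1-7); site 7 is the C-to-A stop-gain that truncates S1TPR into the
inert S1TP.  The lineage-specific flanking genes S1A4 and S1A6 are called
present or absent from breadth of coverage: the fraction of positions in
the gene interval covered at or above a minimum per-base depth.  An
accession's haplotype structure is then the concatenation
{A4-}? {TPR|TP} {-A6}?, and its named allele class (if any) is an
exact-match lookup of the 7-site SNP pattern in a user-supplied catalog.

Inputs use standard dialects: VCF for SNP states, 3-column
chrom/pos/depth text as written by ``samtools depth``, and BED
(0-based half-open) for gene intervals, converted internally to the
1-based inclusive coordinates of the depth files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .model import ConfigError

__all__ = [
    "UntypableError",
    "SnpSite",
    "SnpPanelDef",
    "DEFAULT_PANEL",
    "DepthProfile",
    "PresenceCall",
    "HaplotypeCall",
    "STRUCTURE_LABELS",
    "call_presence",
    "type_tpr",
    "classify_structure",
    "classify_allele",
    "load_catalog",
    "read_depth_tsv",
    "read_bed_intervals",
    "extract_profile",
    "read_snp_states",
    "type_accession",
    "classify_panel",
    "summarize_calls",
]

#: All recognisable haplotype structures.
STRUCTURE_LABELS = (
    "TP",
    "TPR",
    "A4-TP",
    "TP-A6",
    "A4-TP-A6",
    "A4-TPR",
    "TPR-A6",
    "A4-TPR-A6",
)


class UntypableError(ValueError):
    """The SNP states do not permit a TPR/TP call (missing or unexpected)."""


@dataclass(frozen=True)
class SnpSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for state in (self.ref, self.alt):
            if len(state) != 1 or state not in "ACGT":
                raise ConfigError(f"panel states must be single nucleotides, got {state!r}")


@dataclass(frozen=True)
class SnpPanelDef:
    """The ordered 7-site S1TPR/S1TP diagnostic panel.

    Site 7 (the last) is the stop-gain site: its reference state (C)
    marks a full-length S1TPR, the alternate state (A) the truncated
    S1TP.
    """

    sites: tuple[SnpSite, ...]

    def __post_init__(self) -> None:
        if len(self.sites) != 7:
            raise ConfigError(f"the panel must have exactly 7 sites, got {len(self.sites)}")

    @property
    def stop_gain_site(self) -> SnpSite:
        return self.sites[6]

    def site_index(self, chrom: str, pos: int) -> int | None:
        for i, s in enumerate(self.sites):
            if s.chrom == chrom and s.pos == pos:
                return i
        return None


#: Panel on the forward strand of a synthetic S1-g reference layout; the
#: seven sites fall inside the S1TPR gene interval used by the data
#: simulator.  Site 7 ref C / alt A is the stop-gain.
DEFAULT_PANEL = SnpPanelDef(
    sites=(
        SnpSite("S1_region", 3101, "G", "T"),
        SnpSite("S1_region", 3205, "A", "G"),
        SnpSite("S1_region", 3310, "C", "T"),
        SnpSite("S1_region", 3422, "T", "C"),
        SnpSite("S1_region", 3518, "G", "A"),
        SnpSite("S1_region", 3633, "T", "G"),
        SnpSite("S1_region", 3707, "C", "A"),
    )
)


@dataclass(frozen=True)
class DepthProfile:
    """Per-position read depths over one gene interval (1-based inclusive)."""

    gene: str
    start: int  # 1-based first position
    depths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.depths) == 0:
            raise ValueError(f"depth profile for {self.gene!r} is empty")
        if any(d < 0 for d in self.depths):
            raise ValueError("depths must be non-negative")

    @property
    def end(self) -> int:
        return self.start + len(self.depths) - 1


@dataclass(frozen=True)
class PresenceCall:
    gene: str
    breadth: float
    call: str  # "present" | "absent"

    @property
    def present(self) -> bool:
        return self.call == "present"


@dataclass(frozen=True)
class HaplotypeCall:
    """One accession's typed S1 structure."""

    accession: str
    tpr_state: str  # "TPR" | "TP" | "untypable"
    a4: PresenceCall
    a6: PresenceCall
    structure: str  # one of STRUCTURE_LABELS or "untypable"
    snp_pattern: str  # 7 characters, "N" for missing
    allele: str  # catalog name, "novel", or "untypable"


# ---------------------------------------------------------------------------
# Core calls
# ---------------------------------------------------------------------------


def call_presence(
    profile: DepthProfile, min_depth: int = 2, breadth_threshold: float = 0.8
) -> PresenceCall:
    """Breadth-of-coverage presence call for one gene.

    breadth = fraction of interval positions with depth >= min_depth;
    the gene is called present iff breadth >= breadth_threshold.
    """
    depths = np.asarray(profile.depths)
    breadth = float(np.mean(depths >= min_depth))
    call = "present" if breadth >= breadth_threshold else "absent"
    return PresenceCall(gene=profile.gene, breadth=breadth, call=call)


def type_tpr(snp_states: str | Sequence[str], panel: SnpPanelDef = DEFAULT_PANEL) -> str:
    """TPR/TP call from the stop-gain site (site 7) of a 7-state vector.

    The panel's reference state there means full-length TPR, the
    alternate state the truncated TP.  Anything else (missing data, a
    third nucleotide) raises :class:`UntypableError`.
    """
    states = list(snp_states)
    if len(states) != 7:
        raise UntypableError(f"expected 7 SNP states, got {len(states)}")
    site = panel.stop_gain_site
    state = states[6]
    if state == site.ref:
        return "TPR"
    if state == site.alt:
        return "TP"
    raise UntypableError(
        f"state {state!r} at the stop-gain site is neither {site.ref!r} (TPR) "
        f"nor {site.alt!r} (TP)"
    )


def classify_structure(a4: PresenceCall, a6: PresenceCall, tpr_state: str) -> str:
    """Concatenated structure label {A4-}? {TPR|TP} {-A6}? from the calls."""
    if tpr_state not in ("TPR", "TP"):
        raise ValueError(f"tpr_state must be 'TPR' or 'TP', got {tpr_state!r}")
    label = tpr_state
    if a4.present:
        label = "A4-" + label
    if a6.present:
        label = label + "-A6"
    return label


def classify_allele(
    snp_pattern: str | Sequence[str],
    structure: str,
    catalog: Sequence[Mapping],
) -> str:
    """Exact-match lookup of (structure, 7-site pattern) in the allele catalog.

    Catalog entries are mappings with keys ``name``, ``structure`` and
    ``pattern`` (a 7-character state string).  Duplicate
    (structure, pattern) keys are a configuration error; a pattern not
    in the catalog returns "novel".
    """
    pattern = "".join(snp_pattern)
    seen: dict[tuple[str, str], str] = {}
    for entry in catalog:
        try:
            key = (str(entry["structure"]), str(entry["pattern"]))
            name = str(entry["name"])
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed catalog entry {entry!r}: {exc}") from exc
        if len(key[1]) != 7:
            raise ConfigError(f"catalog pattern {key[1]!r} is not 7 states long")
        if key in seen:
            raise ConfigError(
                f"duplicate catalog pattern {key[1]!r} for structure {key[0]!r}"
            )
        seen[key] = name
    return seen.get((structure, pattern), "novel")


def load_catalog(path) -> list[dict]:
    """Read an allele catalog from YAML or JSON (a list under key 'alleles')."""
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if isinstance(doc, Mapping):
        doc = doc.get("alleles", [])
    if not isinstance(doc, list):
        raise ConfigError("allele catalog must be a list of entries")
    return list(doc)


# ---------------------------------------------------------------------------
# File input (samtools-depth TSV, BED, VCF)
# ---------------------------------------------------------------------------


def read_depth_tsv(path) -> pd.DataFrame:
    """Read 3-column chrom/pos/depth text (samtools-depth dialect, no header)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "depth"],
            dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "pos": pd.Series(dtype=np.int64),
                           "depth": pd.Series(dtype=np.int64)})
    return df


def read_bed_intervals(path) -> dict[str, tuple[str, int, int]]:
    """Gene intervals from BED, converted to 1-based inclusive coordinates.

    BED is 0-based half-open: a record (chrom, start, end, name) covers
    1-based positions start+1 .. end.  Returns {name: (chrom, first, last)}.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ConfigError("gene BED needs 4 columns: chrom, start, end, name")
    out: dict[str, tuple[str, int, int]] = {}
    for _, row in df.iterrows():
        chrom, start, end, name = str(row[0]), int(row[1]), int(row[2]), str(row[3])
        if end <= start:
            raise ConfigError(f"empty BED interval for {name!r}")
        out[name] = (chrom, start + 1, end)
    return out


def extract_profile(
    depth: pd.DataFrame, gene: str, interval: tuple[str, int, int]
) -> DepthProfile:
    """Depth profile over one gene interval; uncovered positions count as 0.

    ``samtools depth`` omits zero-depth positions unless run with -a;
    filling the gaps with 0 makes both dialects equivalent.
    """
    chrom, first, last = interval
    length = last - first + 1
    depths = np.zeros(length, dtype=np.int64)
    sel = depth[(depth["chrom"] == chrom) & (depth["pos"].between(first, last))]
    depths[sel["pos"].to_numpy() - first] = sel["depth"].to_numpy()
    return DepthProfile(gene=gene, start=first, depths=tuple(int(d) for d in depths))


def read_snp_states(vcf_path, panel: SnpPanelDef = DEFAULT_PANEL) -> dict[str, str]:
    """Per-sample 7-character SNP state vectors from a VCF.

    Only records at the panel's sites are read; everything else is
    ignored.  A missing or heterozygous genotype yields "N" at that
    site (inbred accessions are expected to be homozygous).
    """
    patterns: dict[str, list[str]] = {}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        for name in samples:
            patterns[name] = ["N"] * 7
        for rec in vcf:
            idx = panel.site_index(rec.chrom, rec.pos)
            if idx is None:
                continue
            alleles = (rec.ref,) + tuple(rec.alts or ())
            for name in samples:
                gt = rec.samples[name].get("GT", (None,))
                if gt is None or any(a is None for a in gt):
                    continue
                if len(set(gt)) != 1:
                    continue  # heterozygous call: ambiguous for an inbred line
                state = alleles[gt[0]]
                if state is not None and len(state) == 1:
                    patterns[name][idx] = state
    return {name: "".join(states) for name, states in patterns.items()}


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def type_accession(
    accession: str,
    snp_pattern: str,
    a4_profile: DepthProfile,
    a6_profile: DepthProfile,
    catalog: Sequence[Mapping] | None = None,
    min_depth: int = 2,
    breadth_threshold: float = 0.8,
) -> HaplotypeCall:
    """Full typing of one accession from its SNP pattern and depth profiles."""
    a4 = call_presence(a4_profile, min_depth, breadth_threshold)
    a6 = call_presence(a6_profile, min_depth, breadth_threshold)
    try:
        tpr_state = type_tpr(snp_pattern)
    except UntypableError:
        return HaplotypeCall(
            accession=accession,
            tpr_state="untypable",
            a4=a4,
            a6=a6,
            structure="untypable",
            snp_pattern=snp_pattern,
            allele="untypable",
        )
    structure = classify_structure(a4, a6, tpr_state)
    allele = (
        classify_allele(snp_pattern, structure, catalog)
        if catalog is not None
        else "novel"
    )
    return HaplotypeCall(
        accession=accession,
        tpr_state=tpr_state,
        a4=a4,
        a6=a6,
        structure=structure,
        snp_pattern=snp_pattern,
        allele=allele,
    )


def classify_panel(
    accessions: Mapping[str, Mapping[str, Path | str]],
    bed_path,
    panel: SnpPanelDef = DEFAULT_PANEL,
    catalog: Sequence[Mapping] | None = None,
    min_depth: int = 2,
    breadth_threshold: float = 0.8,
) -> pd.DataFrame:
    """Type a panel of accessions given per-accession VCF and depth files.

    ``accessions`` maps accession id to {"vcf": path, "depth": path}.
    Gene intervals for S1A4 and S1A6 come from the BED file.  Returns a
    table with one row per accession: tpr_state, A4/A6 calls and
    breadths, structure, SNP pattern, allele class.
    """
    intervals = read_bed_intervals(bed_path)
    for gene in ("S1A4", "S1A6"):
        if gene not in intervals:
            raise ConfigError(f"gene BED lacks an interval named {gene!r}")
    rows = []
    for acc, files in accessions.items():
        states = read_snp_states(files["vcf"], panel)
        if len(states) == 1:
            pattern = next(iter(states.values()))
        else:
            pattern = states.get(acc, "N" * 7)
        depth = read_depth_tsv(files["depth"])
        a4_profile = extract_profile(depth, "S1A4", intervals["S1A4"])
        a6_profile = extract_profile(depth, "S1A6", intervals["S1A6"])
        call = type_accession(
            acc, pattern, a4_profile, a6_profile, catalog, min_depth, breadth_threshold
        )
        rows.append(
            {
                "accession": call.accession,
                "tpr_state": call.tpr_state,
                "a4_breadth": call.a4.breadth,
                "a4_call": call.a4.call,
                "a6_breadth": call.a6.breadth,
                "a6_call": call.a6.call,
                "structure": call.structure,
                "snp_pattern": call.snp_pattern,
                "allele": call.allele,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "tpr_state",
            "a4_breadth",
            "a4_call",
            "a6_breadth",
            "a6_call",
            "structure",
            "snp_pattern",
            "allele",
        ],
    )


def summarize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Accession counts per (structure, allele) class."""
    return (
        calls.groupby(["structure", "allele"], sort=True)
        .size()
        .reset_index(name="n_accessions")
    )
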