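"""GGACH/DRACH motif counting, canonical-isoform selection and densities.

m6A is a transcript mark, so all scanning happens on the spliced sense
strand; genomic minus-strand genes are reverse-complemented before the scan.
Overlapping matches are counted. U and T are treated as identical; N never
matches.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import TranscriptModel, chromosome_class

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: the 18 DRACH 5-mers ([AGT][AG]AC[ACT])
DRACH_5MERS = tuple(
    sorted(d + r + "AC" + h for d in "AGT" for r in "AG" for h in "ACT")
)

#: default strong/weak partition of DRACH: strong = the GGACH family
STRONG_DRACH = ("GGACA", "GGACC", "GGACT")
WEAK_DRACH = tuple(m for m in DRACH_5MERS if m not in STRONG_DRACH)


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern into an overlap-aware regex."""
    body = "".join(f"[{IUPAC[c.upper()]}]" for c in pattern)
    return re.compile(f"(?={body})")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def find_motifs(seq: str, pattern: str) -> list[int]:
    """Start positions of (possibly overlapping) matches of an IUPAC pattern."""
    rx = iupac_regex(pattern)
    return [m.start() for m in rx.finditer(_normalize(seq))]


def count_motifs(seq: str, pattern: str) -> int:
    return len(find_motifs(seq, pattern))


# ---------------------------------------------------------------------------
# Canonical isoform selection
# ---------------------------------------------------------------------------

def select_canonical_isoforms(
    transcripts: Iterable[TranscriptModel],
    max_tsl: int = 3,
    max_level: int = 2,
    require_ccds: bool = True,
) -> tuple[list[TranscriptModel], int]:
    """One isoform per gene: filter by annotation-quality flags, then pick
    the longest spliced transcript (ties by smallest transcript_id).

    A transcript_support_level of None (e.g. "NA") fails the TSL criterion.
    Returns the selection plus the number of genes with no surviving isoform.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    genes_seen = set()
    for t in transcripts:
        genes_seen.add(t.gene_id)
        tsl_ok = t.transcript_support_level is not None and t.transcript_support_level <= max_tsl
        level_ok = t.level is not None and t.level <= max_level
        ccds_ok = (t.ccds_id is not None) or not require_ccds
        if tsl_ok and level_ok and ccds_ok:
            by_gene.setdefault(t.gene_id, []).append(t)
    chosen = []
    for gene_id in sorted(by_gene):
        cands = by_gene[gene_id]
        cands.sort(key=lambda t: (-t.spliced_length, t.transcript_id))
        chosen.append(cands[0])
    n_excluded = len(genes_seen) - len(chosen)
    return chosen, n_excluded


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def region_density(
    transcripts: Iterable[TranscriptModel],
    genome: Mapping[str, str],
    pattern: str,
    region_class: str,
) -> pd.DataFrame:
    """Per-gene motif density in a region class.

    density = 1000 * (sum of counts over fragments) / (sum of fragment
    lengths); genes with zero total region length get NaN and a flag.
    """
    rows = []
    for t in transcripts:
        seq = t.region_sequence(genome, region_class)
        length = len(seq)
        count = count_motifs(seq, pattern) if length else 0
        rows.append(
            {
                "gene_id": t.gene_id,
                "chrom": t.chrom,
                "region": region_class,
                "count": count,
                "length": length,
                "density_per_kb": 1000.0 * count / length if length else np.nan,
                "undefined": length == 0,
            }
        )
    return pd.DataFrame(rows)


def exonic_density(
    transcripts: Iterable[TranscriptModel],
    genome: Mapping[str, str],
    pattern: str,
) -> pd.DataFrame:
    """Per-gene motif density over the full spliced transcript (exons)."""
    rows = []
    for t in transcripts:
        seq = t.spliced_sequence(genome)
        count = count_motifs(seq, pattern)
        rows.append(
            {
                "gene_id": t.gene_id,
                "chrom": t.chrom,
                "count": count,
                "length": len(seq),
                "density_per_kb": 1000.0 * count / len(seq) if seq else np.nan,
            }
        )
    return pd.DataFrame(rows)


def scan_transcript_motifs(
    transcripts: Iterable[TranscriptModel],
    genome: Mapping[str, str],
    pattern: str = "GGACH",
    anchor_offset: int = 2,
) -> pd.DataFrame:
    """Positions of motif matches on spliced transcripts.

    ``anchor_offset`` marks the methylatable base within the motif (the A of
    GGACH); genomic coordinates refer to that base.
    """
    rows = []
    for t in transcripts:
        seq = t.spliced_sequence(genome)
        for start in find_motifs(seq, pattern):
            anchor_tx = start + anchor_offset
            rows.append(
                {
                    "gene_id": t.gene_id,
                    "chrom": t.chrom,
                    "strand": t.strand,
                    "tx_pos": anchor_tx,
                    "pos": t.transcript_to_genomic(anchor_tx),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tx_pos", "pos"])


def drach_subset_density(
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    strong_set: Sequence[str] = STRONG_DRACH,
    weak_set: Sequence[str] = WEAK_DRACH,
    region_class: str | None = None,
    x_aliases: tuple[str, ...] = ("X", "chrX"),
) -> dict:
    """Strong- vs weak-DRACH densities with an X-vs-autosome test per subset.

    The two 5-mer sets must not overlap. With ``region_class`` None the scan
    covers the full spliced transcript.
    """
    strong = {m.upper().replace("U", "T") for m in strong_set}
    weak = {m.upper().replace("U", "T") for m in weak_set}
    if strong & weak:
        raise ValueError(f"strong/weak DRACH sets overlap: {sorted(strong & weak)}")

    def _density(subset: set[str]) -> pd.DataFrame:
        rows = []
        for t in transcripts:
            seq = (
                t.spliced_sequence(genome)
                if region_class is None
                else t.region_sequence(genome, region_class)
            )
            count = sum(count_motifs(seq, m) for m in subset)
            rows.append(
                {
                    "gene_id": t.gene_id,
                    "chrom_class": chromosome_class(t.chrom, x_aliases),
                    "count": count,
                    "length": len(seq),
                    "density_per_kb": 1000.0 * count / len(seq) if seq else np.nan,
                }
            )
        return pd.DataFrame(rows)

    out = {"strong": _density(strong), "weak": _density(weak)}
    pvals = {}
    for label, df in out.items():
        d = df.dropna(subset=["density_per_kb"])
        x = d.loc[d["chrom_class"] == "X", "density_per_kb"]
        a = d.loc[d["chrom_class"] == "autosome", "density_per_kb"]
        if len(x) and len(a):
            pvals[label] = stats.mannwhitneyu(x, a, alternative="two-sided").pvalue
        else:
            pvals[label] = np.nan
    labels = [k for k, v in pvals.items() if np.isfinite(v)]
    if labels:
        adj = multipletests([pvals[k] for k in labels], method="fdr_bh")[1]
        padj = dict(zip(labels, adj))
    else:
        padj = {}
    return {"densities": out, "p": pvals, "p_adj": padj}


# ---------------------------------------------------------------------------
# Ortholog and gene-set comparisons
# ---------------------------------------------------------------------------

def ortholog_group_compare(
    densities_by_species: Mapping[str, pd.Series],
    ortholog_map: pd.DataFrame,
    mouse_chromosome_class: pd.Series,
    reference_species: str = "mouse",
) -> pd.DataFrame:
    """Compare exonic motif densities between genes grouped by the *mouse*
    chromosome class, in mouse and in each outgroup species.

    ``ortholog_map`` has columns mouse_gene/species/ortholog_gene and is
    restricted to one-to-one pairs; many-to-many rows are dropped (counted).
    Only mouse genes with an ortholog in every species are used.
    """
    omap = ortholog_map.copy()
    n_dropped = 0
    for col, group in (("mouse_gene", ["species", "mouse_gene"]),
                       ("ortholog_gene", ["species", "ortholog_gene"])):
        dup = omap.duplicated(subset=group, keep=False)
        n_dropped += int(dup.sum())
        omap = omap.loc[~dup]
    species = sorted(omap["species"].unique())
    per_species = {s: omap.loc[omap["species"] == s] for s in species}
    common = None
    for s in species:
        genes = set(per_species[s]["mouse_gene"])
        common = genes if common is None else (common & genes)
    common = common or set()

    rows = []
    groups = {
        s: per_species[s].set_index("mouse_gene")["ortholog_gene"] for s in species
    }
    universe = sorted(common)
    classes = mouse_chromosome_class.reindex(universe)
    for s in [reference_species] + species:
        if s == reference_species:
            dens = densities_by_species[reference_species].reindex(universe)
        else:
            if s not in densities_by_species:
                continue
            dens = densities_by_species[s].reindex(groups[s].reindex(universe)).to_numpy()
            dens = pd.Series(dens, index=universe)
        d = pd.DataFrame({"density": dens, "class": classes}).dropna()
        x = d.loc[d["class"] == "X", "density"]
        a = d.loc[d["class"] == "autosome", "density"]
        p = (
            stats.mannwhitneyu(x, a, alternative="two-sided").pvalue
            if len(x) and len(a)
            else np.nan
        )
        rows.append(
            {
                "species": s,
                "n_genes": len(d),
                "median_x": float(x.median()) if len(x) else np.nan,
                "median_autosome": float(a.median()) if len(a) else np.nan,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).drop_duplicates(subset="species")
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out.attrs["n_dropped_many_to_many"] = n_dropped
    out.attrs["n_common_genes"] = len(universe)
    return out


def geneset_density_compare(
    densities: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    k_lowest: int = 200,
) -> dict:
    """Each named gene set vs its complement in the density universe
    (rank-sum, BH across sets), plus the k lowest-density genes
    (ties broken by gene_id) for downstream enrichment tools.
    """
    universe = densities.dropna()
    rows = []
    for name, genes in gene_sets.items():
        members = universe.index.intersection(pd.Index(genes))
        rest = universe.index.difference(members)
        if len(members) == 0:
            rows.append({"set": name, "n": 0, "p": np.nan, "flag": "empty_intersection"})
            continue
        if len(rest) == 0:
            p = 1.0
        else:
            p = stats.mannwhitneyu(
                universe.loc[members], universe.loc[rest], alternative="two-sided"
            ).pvalue
        rows.append(
            {
                "set": name,
                "n": len(members),
                "median_set": float(universe.loc[members].median()),
                "median_rest": float(universe.loc[rest].median()) if len(rest) else np.nan,
                "p": p,
                "flag": "",
            }
        )
    df = pd.DataFrame(rows, columns=["set", "n", "median_set", "median_rest", "p", "flag"])
    ok = df["p"].notna()
    df["p_adj"] = np.nan
    if ok.any():
        df.loc[ok, "p_adj"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    ranked = universe.reset_index()
    ranked.columns = ["gene_id", "density"]
    ranked = ranked.sort_values(["density", "gene_id"]).head(k_lowest)
    return {"comparisons": df, "lowest_density_genes": ranked["gene_id"].tolist()}
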