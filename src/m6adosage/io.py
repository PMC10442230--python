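"""Readers and writers for the standard formats used by the pipeline.

GTF is 1-based inclusive on disk and converted exactly to the internal
0-based half-open convention (and back on write). BED6 is 0-based half-open.
All tables are plain TSV with headers.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .annotation import REGION_CLASSES, TranscriptModel

_REGION_FEATURES = {"five_prime_utr": "utr5", "CDS": "cds", "three_prime_utr": "utr3"}
_FEATURE_OF_REGION = {v: k for k, v in _REGION_FEATURES.items()}

CONVERSION_COLUMNS = ["utr_id", "time_h", "condition", "replicate", "t_coverage", "tc_count"]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def write_annotation(path: str, transcripts: Iterable[TranscriptModel]) -> None:
    """Write transcripts as GTF (gene/transcript/exon/region features)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.ccds_id is not None:
                attrs += f' ccdsid "{t.ccds_id}";'
            if t.level is not None:
                attrs += f' level "{t.level}";'
            tsl = "NA" if t.transcript_support_level is None else t.transcript_support_level
            attrs += f' transcript_support_level "{tsl}";'
            span = (min(a for a, _ in t.exons), max(b for _, b in t.exons))
            rows = [("transcript", span)]
            rows += [("exon", iv) for iv in t.exons]
            for cls in REGION_CLASSES:
                rows += [(_FEATURE_OF_REGION[cls], iv) for iv in t.regions.get(cls, [])]
            for feature, (a, b) in rows:
                fh.write(
                    f"{t.chrom}\tm6adosage\t{feature}\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def _parse_tsl(raw) -> int | None:
    try:
        return int(str(raw))
    except (TypeError, ValueError):
        return None  # "NA" and friends fail the <=3 criterion downstream


def read_annotation(path: str) -> tuple[list[TranscriptModel], int]:
    """Read a GTF file into TranscriptModels.

    Returns the models plus the number of records skipped for missing
    mandatory attributes.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    by_tx: dict[str, dict] = {}
    skipped = 0
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "five_prime_utr", "three_prime_utr", "transcript"):
            continue
        try:
            gene_id = feat.attributes["gene_id"][0]
            tx_id = feat.attributes["transcript_id"][0]
        except KeyError:
            skipped += 1
            continue
        rec = by_tx.setdefault(
            tx_id,
            {
                "gene_id": gene_id,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "regions": {cls: [] for cls in REGION_CLASSES},
                "ccds_id": None,
                "tsl": None,
                "level": None,
            },
        )
        iv = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> half-open
        if feat.featuretype == "exon":
            rec["exons"].append(iv)
        elif feat.featuretype in _REGION_FEATURES:
            rec["regions"][_REGION_FEATURES[feat.featuretype]].append(iv)
        if "ccsdid" in feat.attributes:  # pragma: no cover - defensive typo guard
            rec["ccds_id"] = feat.attributes["ccsdid"][0]
        if "ccdsid" in feat.attributes:
            rec["ccds_id"] = feat.attributes["ccdsid"][0]
        if "transcript_support_level" in feat.attributes:
            rec["tsl"] = _parse_tsl(feat.attributes["transcript_support_level"][0])
        if "level" in feat.attributes:
            try:
                rec["level"] = int(feat.attributes["level"][0])
            except ValueError:
                pass
    models = []
    for tx_id, rec in by_tx.items():
        if not rec["exons"]:
            skipped += 1
            continue
        models.append(
            TranscriptModel(
                gene_id=rec["gene_id"],
                transcript_id=tx_id,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                regions={c: v for c, v in rec["regions"].items() if v},
                ccds_id=rec["ccds_id"],
                transcript_support_level=rec["tsl"],
                level=rec["level"],
            )
        )
    return models, skipped


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(path: str, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    fa = Fasta(path, rebuild=True)
    out = {name: str(fa[name][:]).upper() for name in fa.keys()}
    fa.close()
    for ext in (".fai",):
        try:
            os.remove(path + ext)
        except OSError:
            pass
    return out


# ---------------------------------------------------------------------------
# BED6 sites / peaks
# ---------------------------------------------------------------------------

def write_sites(path: str, sites: pd.DataFrame) -> None:
    """Write single-nucleotide sites as BED6 (cols chrom, pos, strand [, name])."""
    df = sites.copy()
    name = df["name"] if "name" in df else "."
    bed = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"].astype(int),
            "end": df["pos"].astype(int) + 1,
            "name": name,
            "score": 0,
            "strand": df["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_sites(
    path: str, transcripts: list[TranscriptModel] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Read single-nucleotide BED6 records; optionally assign to genes.

    Records whose interval length is not 1 are rejected and counted.
    Assignment requires strand-matched exonic overlap with a transcript;
    everything else lands in the ``orphan`` ledger.
    """
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    bad = bed["end"] - bed["start"] != 1
    ledger = {"rejected_length": int(bad.sum()), "orphans": 0}
    sites = bed.loc[~bad, ["chrom", "start", "strand", "name"]].rename(
        columns={"start": "pos"}
    )
    sites = sites.reset_index(drop=True)
    if transcripts is not None:
        sites, n_orphan = assign_sites_to_genes(sites, transcripts)
        ledger["orphans"] = n_orphan
    return sites, ledger


def assign_sites_to_genes(
    sites: pd.DataFrame, transcripts: list[TranscriptModel]
) -> tuple[pd.DataFrame, int]:
    """Strand-matched exonic assignment of single-nucleotide sites to genes.

    Antisense or intergenic sites are dropped (counted as orphans).
    """
    index: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for t in transcripts:
        lst = index.setdefault((t.chrom, t.strand), [])
        for a, b in t.exons:
            lst.append((a, b, t.gene_id))
    arrays = {}
    for key, lst in index.items():
        lst.sort()
        starts = np.array([a for a, _, _ in lst])
        ends = np.array([b for _, b, _ in lst])
        genes = np.array([g for _, _, g in lst])
        max_len = int((ends - starts).max())
        arrays[key] = (starts, ends, genes, max_len)

    assigned = []
    n_orphan = 0
    for row in sites.itertuples(index=False):
        key = (row.chrom, row.strand)
        gene = None
        if key in arrays:
            starts, ends, genes, max_len = arrays[key]
            i = int(np.searchsorted(starts, row.pos, side="right")) - 1
            # walk back over exons starting within max_len (overlaps may nest)
            while i >= 0 and starts[i] > row.pos - max_len:
                if ends[i] > row.pos:
                    gene = genes[i]
                    break
                i -= 1
        if gene is None:
            n_orphan += 1
        else:
            assigned.append((row.chrom, row.pos, row.strand, gene))
    out = pd.DataFrame(assigned, columns=["chrom", "pos", "strand", "gene_id"])
    return out, n_orphan


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_table(path: str, kind: str) -> pd.DataFrame:
    """Read and validate a TSV table of a known kind.

    kinds: ``counts`` (gene_id + numeric sample columns), ``tpm``/``rpkm``
    (gene_id + numeric columns), ``conversions`` (SLAM conversion rows),
    ``orthologs`` (mouse_gene, species, ortholog_gene).
    """
    df = pd.read_csv(path, sep="\t")
    if kind == "conversions":
        missing = [c for c in CONVERSION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"conversion table missing columns: {missing}")
        bad = df["tc_count"] > df["t_coverage"]
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} conversion rows with tc_count > t_coverage"
            )
        if (df["time_h"] < 0).any():
            raise ValueError("negative time_h in conversion table")
        return df
    if kind in ("counts", "tpm", "rpkm"):
        if "gene_id" not in df.columns:
            raise ValueError(f"{kind} table missing column: gene_id")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene row in {kind} table: {dup}")
        value_cols = [c for c in df.columns if c != "gene_id"]
        for c in value_cols:
            df[c] = pd.to_numeric(df[c])
        return df.set_index("gene_id")
    if kind == "orthologs":
        for c in ("mouse_gene", "species", "ortholog_gene"):
            if c not in df.columns:
                raise ValueError(f"ortholog table missing column: {c}")
        return df
    raise ValueError(f"unknown table kind {kind!r}")


def write_table(path: str, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
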