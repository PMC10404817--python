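"""Core containers and plain-text readers/writers.

Every genomic coordinate inside brainreg is 0-based half-open (BED
convention). Formats that are 1-based inclusive (GTF/GFF) are converted at
the boundary. Readers validate strictly and raise :class:`FormatError` /
:class:`ConsistencyError` instead of silently coercing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, FormatError, InputError

# Columns the expression metadata may carry; ``group`` must be one of these.
GROUPS = ("brain", "nonbrain")

META_REQUIRED = ("species", "tissue", "group")


# ---------------------------------------------------------------------------
# Expression study
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """A gene x sample integer count table plus per-sample metadata.

    ``counts``: DataFrame indexed by gene_id, columns = sample ids.
    ``sample_meta``: DataFrame indexed by sample_id with at least
    species/tissue/group, optionally age, sex, rin, uniquely_mapped_reads,
    unique_map_rate.
    ``gene_lengths``: optional Series of gene lengths in bp (for TPM/FPKM).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_lengths: Optional[pd.Series] = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise ConsistencyError(f"duplicate gene id {dup!r} in counts")
        if list(c.columns) != list(self.sample_meta.index):
            missing = set(c.columns) ^ set(self.sample_meta.index)
            raise ConsistencyError(
                "counts columns and metadata sample ids differ: "
                f"{sorted(missing)[:5]}"
            )
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = np.argwhere(vals != np.round(vals))[0]
                raise FormatError(
                    "<counts>", int(bad[0]) + 1,
                    f"non-integer count at gene {c.index[bad[0]]!r} "
                    f"sample {c.columns[bad[1]]!r}")
            self.counts = c = c.astype(np.int64)
            vals = c.to_numpy()
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise FormatError(
                "<counts>", int(bad[0]) + 1,
                f"negative count at gene {c.index[bad[0]]!r} "
                f"sample {c.columns[bad[1]]!r}")
        for col in META_REQUIRED:
            if col not in self.sample_meta.columns:
                raise ConsistencyError(f"sample metadata lacks column {col!r}")
        bad_groups = set(self.sample_meta["group"]) - set(GROUPS)
        if bad_groups:
            raise ConsistencyError(
                f"sample group(s) {sorted(bad_groups)} not in {GROUPS}")
        if self.gene_lengths is not None:
            gl = self.gene_lengths.reindex(c.index)
            if gl.isna().any():
                raise ConsistencyError("gene_lengths missing some genes")
            if (gl <= 0).any():
                raise ConsistencyError("gene_lengths must be positive")
            self.gene_lengths = gl.astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, keep: list[str]) -> "ExpressionStudy":
        return ExpressionStudy(
            self.counts[keep], self.sample_meta.loc[keep],
            self.gene_lengths)

    def subset_genes(self, keep) -> "ExpressionStudy":
        keep = list(keep)
        return ExpressionStudy(
            self.counts.loc[keep], self.sample_meta,
            None if self.gene_lengths is None else self.gene_lengths.loc[keep])


def read_counts(counts_path, meta_path, lengths_path=None) -> ExpressionStudy:
    """Read a counts TSV (first column gene ids, header sample ids) plus a
    companion metadata TSV indexed by sample_id."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    for j, col in enumerate(counts.columns):
        colvals = counts[col]
        if not np.issubdtype(colvals.dtype, np.number):
            bad = colvals[pd.to_numeric(colvals, errors="coerce").isna()]
            raise FormatError(counts_path, 0,
                              f"non-numeric count in column {col!r}: "
                              f"{bad.iloc[0]!r} at gene {bad.index[0]!r}")
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(arr != np.round(arr))[0]
        raise FormatError(counts_path, int(i) + 2,
                          f"non-integer count at gene {counts.index[i]!r} "
                          f"column {counts.columns[j]!r}")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise FormatError(counts_path, int(i) + 2,
                          f"negative count at gene {counts.index[i]!r} "
                          f"column {counts.columns[j]!r}")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if set(counts.columns) != set(meta.index):
        raise ConsistencyError(
            f"{counts_path} and {meta_path} disagree on sample ids: "
            f"{sorted(set(counts.columns) ^ set(meta.index))[:5]}")
    meta = meta.loc[counts.columns]
    counts.index.name = None
    meta.index.name = None
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = lt.iloc[:, 0]
    return ExpressionStudy(counts.astype(np.int64), meta, lengths)


def write_counts(study: ExpressionStudy, counts_path, meta_path,
                 lengths_path=None) -> None:
    study.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    study.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")
    if lengths_path is not None and study.gene_lengths is not None:
        study.gene_lengths.rename("length").to_csv(
            lengths_path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Interval sets (peaks, RECNEs, anchors)
# ---------------------------------------------------------------------------


@dataclass
class IntervalSet:
    """Genomic intervals in 0-based half-open coordinates.

    ``df`` columns: chrom, start, end, name; optional strand, sample_id.
    Strand is optional on interval sets (peaks are unstranded signals) and
    ignored by intersection.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise InputError(f"IntervalSet lacks column {col!r}")
        if "name" not in df.columns:
            df["name"] = [f"iv{i}" for i in range(len(df))]
        if (df["start"] >= df["end"]).any():
            i = int(np.argmax((df["start"] >= df["end"]).to_numpy()))
            raise InputError(
                f"interval {df['name'].iloc[i]!r} has start >= end "
                f"({df['start'].iloc[i]} >= {df['end'].iloc[i]})")
        if (df["chrom"].astype(str) == "").any():
            raise InputError("empty chrom name in IntervalSet")
        if df["name"].duplicated().any():
            dup = df["name"][df["name"].duplicated()].iloc[0]
            raise InputError(f"duplicate interval name {dup!r}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.df = df

    def __len__(self):
        return len(self.df)

    @classmethod
    def from_records(cls, records, sample_id=None) -> "IntervalSet":
        """records: iterable of (chrom, start, end[, name[, strand]])."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            row = {"chrom": rec[0], "start": rec[1], "end": rec[2]}
            if len(rec) > 3:
                row["name"] = rec[3]
            if len(rec) > 4:
                row["strand"] = rec[4]
            rows.append(row)
        df = pd.DataFrame(rows)
        if sample_id is not None:
            df["sample_id"] = sample_id
        return cls(df)


def read_bed(path) -> IntervalSet:
    """Read a BED file (>=3 tab-separated columns; name/score/strand honored)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(path, lineno, "fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(path, lineno,
                                  "start/end are not integers") from None
            if start >= end:
                raise FormatError(path, lineno, f"start >= end ({start} >= {end})")
            row = {"chrom": chrom, "start": start, "end": end}
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4 and parts[4] not in (".", ""):
                row["score"] = float(parts[4])
            if len(parts) > 5 and parts[5] in ("+", "-"):
                row["strand"] = parts[5]
            rows.append(row)
    if not rows:
        return IntervalSet(pd.DataFrame(
            {"chrom": [], "start": [], "end": [], "name": []}))
    return IntervalSet(pd.DataFrame(rows))


def write_bed(ivset: IntervalSet, path) -> None:
    df = ivset.df
    cols = ["chrom", "start", "end", "name"]
    out = df[cols].copy()
    if "score" in df.columns or "strand" in df.columns:
        out["score"] = df["score"] if "score" in df.columns else 0
        out["strand"] = df["strand"] if "strand" in df.columns else "."
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotation:
    """Gene bodies with mandatory strand; TSS derived from strand.

    tss = start on '+', end - 1 on '-' (0-based base position of the first
    transcribed base).
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        for col in ("gene_id", "chrom", "start", "end", "strand"):
            if col not in df.columns:
                raise InputError(f"GeneAnnotation lacks column {col!r}")
        if df["gene_id"].duplicated().any():
            dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
            raise InputError(f"duplicate gene_id {dup!r}")
        if (df["start"] >= df["end"]).any():
            raise InputError("gene with start >= end")
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise InputError(
                f"gene {df['gene_id'][bad].iloc[0]!r} has invalid strand "
                f"{df['strand'][bad].iloc[0]!r}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
        self.df = df.set_index("gene_id", drop=False)

    def __len__(self):
        return len(self.df)


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_gene_annotation(path) -> GeneAnnotation:
    """Read genes from a 5-column TSV (gene_id chrom start end strand,
    0-based half-open) or from GTF/GFF (1-based inclusive, converted)."""
    path = str(path)
    if path.endswith((".gtf", ".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise FormatError(path, lineno, "fewer than 9 GTF columns")
                if parts[2] != "gene":
                    continue
                m = _GTF_GENE_ID.search(parts[8])
                if not m:
                    raise FormatError(path, lineno, "gene line lacks gene_id")
                start1, end1 = int(parts[3]), int(parts[4])
                rows.append({"gene_id": m.group(1), "chrom": parts[0],
                             "start": start1 - 1, "end": end1,
                             "strand": parts[6]})
        return GeneAnnotation(pd.DataFrame(rows))
    df = pd.read_csv(path, sep="\t")
    return GeneAnnotation(df)


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    ann.df[["gene_id", "chrom", "start", "end", "strand"]].to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ortholog map
# ---------------------------------------------------------------------------


@dataclass
class OrthologMap:
    """One-to-one ortholog table: one column per species, one row per
    ancestral gene. No id may appear twice within its species column."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        for col in df.columns:
            if df[col].duplicated().any():
                dup = df[col][df[col].duplicated()].iloc[0]
                raise ConsistencyError(
                    f"gene id {dup!r} appears twice in species column {col!r}")
        self.df = df

    @property
    def species(self) -> list[str]:
        return list(self.df.columns)

    def universe(self, species: str) -> set:
        return set(self.df[species])

    def translate(self, ids, from_species: str, to_species: str):
        """Translate ids between species columns.

        Returns (translated_set, n_dropped) where dropped ids have no
        ortholog row.
        """
        mapping = dict(zip(self.df[from_species], self.df[to_species]))
        ids = set(ids)
        translated = {mapping[g] for g in ids if g in mapping}
        return translated, len(ids) - sum(1 for g in ids if g in mapping)


def read_orthologs(path) -> OrthologMap:
    return OrthologMap(pd.read_csv(path, sep="\t"))


def write_orthologs(omap: OrthologMap, path) -> None:
    omap.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Block coordinate map (liftover stand-in)
# ---------------------------------------------------------------------------


@dataclass
class BlockCoordinateMap:
    """Piecewise mapping between assemblies as equal-length aligned blocks.

    TSV dialect: src_chrom, src_start, src_end, tgt_chrom, tgt_start,
    tgt_end, orientation (+/-). Gaps between source blocks are unmappable.
    Source blocks must be non-overlapping within each chromosome.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        cols = ["src_chrom", "src_start", "src_end",
                "tgt_chrom", "tgt_start", "tgt_end", "orientation"]
        for col in cols:
            if col not in df.columns:
                raise InputError(f"BlockCoordinateMap lacks column {col!r}")
        for c in ("src_start", "src_end", "tgt_start", "tgt_end"):
            df[c] = df[c].astype(np.int64)
        src_len = df["src_end"] - df["src_start"]
        tgt_len = df["tgt_end"] - df["tgt_start"]
        if (src_len <= 0).any() or (tgt_len <= 0).any():
            raise InputError("block with non-positive length")
        if (src_len != tgt_len).any():
            i = int(np.argmax((src_len != tgt_len).to_numpy()))
            raise InputError(
                f"block {i}: source length {src_len.iloc[i]} != target "
                f"length {tgt_len.iloc[i]}")
        if not df["orientation"].isin(["+", "-"]).all():
            raise InputError("orientation must be '+' or '-'")
        df = df.sort_values(["src_chrom", "src_start"]).reset_index(drop=True)
        for chrom, sub in df.groupby("src_chrom"):
            ends = sub["src_end"].to_numpy()
            starts = sub["src_start"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise InputError(
                    f"overlapping source blocks on {chrom}")
        self.df = df
        # per-chromosome arrays for fast queries
        self._by_chrom = {
            chrom: (sub["src_start"].to_numpy(), sub["src_end"].to_numpy(),
                    sub.index.to_numpy())
            for chrom, sub in df.groupby("src_chrom")}

    def __len__(self):
        return len(self.df)

    def map_interval(self, chrom, start, end, min_mapped_fraction=0.95):
        """Map a source interval block-wise to the target assembly.

        Returns (tgt_chrom, tgt_start, tgt_end) covering the span of all
        mapped bases, or None (unmappable) when the mapped fraction falls
        below ``min_mapped_fraction`` or the blocks disagree on target
        chromosome/orientation.
        """
        if start >= end:
            raise InputError(f"start >= end ({start} >= {end})")
        if chrom not in self._by_chrom:
            return None
        starts, ends, idx = self._by_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        mapped = 0
        spans = []
        chroms = set()
        orients = set()
        for i in idx[lo:hi]:
            row = self.df.iloc[i]
            a = max(start, row["src_start"])
            b = min(end, row["src_end"])
            if a >= b:
                continue
            mapped += b - a
            chroms.add(row["tgt_chrom"])
            orients.add(row["orientation"])
            if row["orientation"] == "+":
                off = row["tgt_start"] - row["src_start"]
                spans.append((a + off, b + off))
            else:
                # reverse within block: src p -> tgt_start + (src_end-1-p)
                t_lo = row["tgt_start"] + (row["src_end"] - b)
                t_hi = row["tgt_start"] + (row["src_end"] - a)
                spans.append((t_lo, t_hi))
        if mapped == 0:
            return None
        if mapped / (end - start) < min_mapped_fraction:
            return None
        if len(chroms) > 1 or len(orients) > 1:
            return None
        t_start = min(s for s, _ in spans)
        t_end = max(e for _, e in spans)
        return (chroms.pop(), int(t_start), int(t_end))

    def inverse(self) -> "BlockCoordinateMap":
        """Swap source and target (valid because block lengths are equal)."""
        df = self.df.rename(columns={
            "src_chrom": "tgt_chrom", "src_start": "tgt_start",
            "src_end": "tgt_end", "tgt_chrom": "src_chrom",
            "tgt_start": "src_start", "tgt_end": "src_end"})
        return BlockCoordinateMap(df)

    @classmethod
    def identity(cls, chrom_sizes: dict) -> "BlockCoordinateMap":
        rows = [{"src_chrom": c, "src_start": 0, "src_end": size,
                 "tgt_chrom": c, "tgt_start": 0, "tgt_end": size,
                 "orientation": "+"} for c, size in sorted(chrom_sizes.items())]
        return cls(pd.DataFrame(rows))


def read_block_map(path) -> BlockCoordinateMap:
    cols = ["src_chrom", "src_start", "src_end",
            "tgt_chrom", "tgt_start", "tgt_end", "orientation"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=cols,
                         comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=cols)
    if len(df) and df["src_start"].dtype == object:
        raise FormatError(path, 1, "non-integer coordinates in block map")
    try:
        return BlockCoordinateMap(df)
    except InputError as exc:
        raise FormatError(path, 0, str(exc)) from exc


def write_block_map(bmap: BlockCoordinateMap, path) -> None:
    bmap.df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Chromatin loops (BEDPE)
# ---------------------------------------------------------------------------


@dataclass
class LoopSet:
    """Paired anchors in BEDPE convention; both anchors valid intervals."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        for col in ("chromA", "startA", "endA", "chromB", "startB", "endB"):
            if col not in df.columns:
                raise InputError(f"LoopSet lacks column {col!r}")
        for c in ("startA", "endA", "startB", "endB"):
            df[c] = df[c].astype(np.int64)
        if ((df["startA"] >= df["endA"]) | (df["startB"] >= df["endB"])).any():
            raise InputError("loop anchor with start >= end")
        if "loop_id" not in df.columns:
            df["loop_id"] = [f"loop{i}" for i in range(len(df))]
        self.df = df

    def __len__(self):
        return len(self.df)


def read_loops(path) -> LoopSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(path, lineno, "fewer than 6 BEDPE columns")
            try:
                row = {"chromA": parts[0], "startA": int(parts[1]),
                       "endA": int(parts[2]), "chromB": parts[3],
                       "startB": int(parts[4]), "endB": int(parts[5])}
            except ValueError:
                raise FormatError(path, lineno,
                                  "anchor coordinates not integers") from None
            if row["startA"] >= row["endA"] or row["startB"] >= row["endB"]:
                raise FormatError(path, lineno, "anchor start >= end")
            if len(parts) > 6:
                row["loop_id"] = parts[6]
            if len(parts) > 7 and parts[7] not in (".", ""):
                row["score"] = float(parts[7])
            rows.append(row)
    if not rows:
        return LoopSet(pd.DataFrame(columns=[
            "chromA", "startA", "endA", "chromB", "startB", "endB"]))
    return LoopSet(pd.DataFrame(rows))


def write_loops(loops: LoopSet, path) -> None:
    df = loops.df
    cols = ["chromA", "startA", "endA", "chromB", "startB", "endB", "loop_id"]
    out = df[cols].copy()
    if "score" in df.columns:
        out["score"] = df["score"]
    out.to_csv(path, sep="\t", header=False, index=False)
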