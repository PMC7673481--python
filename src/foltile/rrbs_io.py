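"""Readers and writers for the pipeline's external file formats.

Canonical per-CpG input is Bismark-coverage-style text: six tab-separated
columns (chrom, start, end, percent methylation, count methylated, count
unmethylated) with 1-based inclusive positions.  A methylKit-style dialect
(id, chr, base, strand, coverage, freqC, freqT) is accepted as an alternate
and converted to counts at the boundary.

Coordinate discipline: every in-memory tile or region is 0-based half-open;
1-based input positions are converted exactly once, here.  CpG positions are
kept 1-based in ``SampleMethylome.records`` (they are points, not intervals)
and converted when tiled.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

TISSUES = ("placenta", "cortex")
DIETS = ("Ctrl", "7FD", "10FS", "20FS")
SEXES = ("M", "F", "unknown")

#: feature precedence used whenever a position/tile overlaps several
#: annotations; first match wins.
FEATURE_PRECEDENCE = ("promoter", "exon", "intron")
INTERGENIC = "intergenic"


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


class CpGRecord(NamedTuple):
    """A single CpG observation (1-based position, strand-collapsed)."""

    chrom: str
    pos: int
    count_meth: int
    count_unmeth: int

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth


@dataclass
class SampleMethylome:
    """Per-CpG counts for one sample, sorted and deduplicated.

    ``records`` is a DataFrame with columns chrom, pos, count_meth,
    count_unmeth — sorted by (chrom, pos), no duplicate positions, every
    row with coverage >= 1.
    """

    sample_id: str
    tissue: str
    diet: str
    sex: str = "unknown"
    records: pd.DataFrame = field(default_factory=lambda: _empty_records())

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.diet not in DIETS:
            raise ValueError(f"unknown diet {self.diet!r}; expected one of {DIETS}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEXES}")

    def __len__(self) -> int:
        return len(self.records)

    def iter_records(self) -> Iterable[CpGRecord]:
        for row in self.records.itertuples(index=False):
            yield CpGRecord(row.chrom, int(row.pos), int(row.count_meth), int(row.count_unmeth))


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
         "count_meth": pd.Series(dtype=np.int64), "count_unmeth": pd.Series(dtype=np.int64)}
    )


def _finalize_records(df: pd.DataFrame, destrand: bool = False) -> pd.DataFrame:
    """Sort, merge duplicates additively, drop zero-coverage rows."""
    if len(df) == 0:
        return _empty_records()
    if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
        bad = df.index[(df["count_meth"] < 0) | (df["count_unmeth"] < 0)][0]
        raise FormatError(f"negative count at record {bad}")
    df = (
        df.groupby(["chrom", "pos"], as_index=False, sort=True)[["count_meth", "count_unmeth"]]
        .sum()
    )
    if destrand:
        # merge CpG dyads: a record at pos+1 is folded into pos when pos exists
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        prev_chrom = df["chrom"].shift()
        prev_pos = df["pos"].shift()
        is_partner = (df["chrom"] == prev_chrom) & (df["pos"] == prev_pos + 1)
        anchor = df["pos"].where(~is_partner, (prev_pos).astype("Int64"))
        df = df.assign(pos=anchor.astype(np.int64))
        df = df.groupby(["chrom", "pos"], as_index=False, sort=True)[
            ["count_meth", "count_unmeth"]
        ].sum()
    df = df[(df["count_meth"] + df["count_unmeth"]) >= 1]
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df.astype({"pos": np.int64, "count_meth": np.int64, "count_unmeth": np.int64})


def read_coverage_file(path, sample_id: str, tissue: str, diet: str,
                       sex: str = "unknown", destrand: bool = False) -> SampleMethylome:
    """Read a Bismark-coverage-style file into a :class:`SampleMethylome`.

    Columns: chrom, start (1-based), end, percent methylation, count
    methylated, count unmethylated.  Duplicate positions are merged by
    summing counts; zero-coverage rows are dropped.  With ``destrand=True``
    counts at adjacent positions (pos, pos+1) are summed onto pos,
    collapsing CpG dyads reported per strand.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 tab-separated columns, got {len(parts)}")
            try:
                chrom = parts[0]
                pos = int(parts[1])
                cm = int(parts[4])
                cu = int(parts[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position must be >= 1, got {pos}")
            if cm < 0 or cu < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            rows.append((chrom, pos, cm, cu))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "count_meth", "count_unmeth"])
    return SampleMethylome(sample_id, tissue, diet, sex, _finalize_records(df, destrand=destrand))


def read_methylkit_file(path, sample_id: str, tissue: str, diet: str,
                        sex: str = "unknown", destrand: bool = False) -> SampleMethylome:
    """Read the alternate dialect: id, chr, base, strand, coverage, freqC, freqT.

    freqC/freqT are percentages of cytosine (methylated) and thymine
    (unmethylated) calls; converted to integer counts by rounding
    coverage * freq / 100.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.lower().startswith(("#", "id\t")):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 tab-separated columns, got {len(parts)}")
            try:
                chrom = parts[1]
                pos = int(parts[2])
                cov = int(parts[4])
                freq_c = float(parts[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if cov < 0 or not (0.0 <= freq_c <= 100.0):
                raise FormatError(f"{path}:{lineno}: coverage/frequency out of range")
            cm = int(round(cov * freq_c / 100.0))
            rows.append((chrom, pos, cm, cov - cm))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "count_meth", "count_unmeth"])
    return SampleMethylome(sample_id, tissue, diet, sex, _finalize_records(df, destrand=destrand))


def write_coverage_file(sample: SampleMethylome, path) -> None:
    """Write records back to the six-column coverage dialect (round-trips)."""
    df = sample.records
    cov = df["count_meth"] + df["count_unmeth"]
    pct = np.where(cov > 0, 100.0 * df["count_meth"] / cov.replace(0, 1), 0.0)
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["pos"], "end": df["pos"],
        "pct": np.round(pct, 6), "count_meth": df["count_meth"],
        "count_unmeth": df["count_unmeth"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# DMT BED I/O

DMT_BED_COLUMNS = ["chrom", "start", "end", "name", "delta", "direction", "p_value", "q_value", "magnitude_bin"]


def write_dmt_bed(dmts: pd.DataFrame, path) -> None:
    """Write called DMTs as BED6+ (0-based half-open), one line per tile.

    Expects the DataFrame produced by :func:`foltile.tiling_dm.call_dmts`.
    A commented header line is always written so an empty DMT set still
    produces a parseable file.
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(DMT_BED_COLUMNS) + "\n")
        for row in dmts.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t"
                f"{row.chrom}:{int(row.start)}-{int(row.end)}\t"
                f"{row.delta:.6g}\t{row.direction}\t{row.p_value:.6g}\t{row.q_value:.6g}\t{row.magnitude_bin}\n"
            )


def read_dmt_bed(path) -> pd.DataFrame:
    """Re-parse a DMT BED written by :func:`write_dmt_bed`."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[4]),
                         parts[5], float(parts[6]), float(parts[7]), parts[8]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "delta", "direction",
                                       "p_value", "q_value", "magnitude_bin"])


# ---------------------------------------------------------------------------
# Gene models

@dataclass
class GeneModel:
    """Interval index over (promoter, exon, intron) features.

    Promoters are taken from explicit ``promoter`` records when present;
    otherwise they are derived from transcript/gene records as a window
    around the transcription start site (default 2000 bp upstream to 500 bp
    downstream, strand-aware).
    """

    intervals: pd.DataFrame  # chrom, start, end, feature, gene_id, strand
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if len(self.intervals) and (self.intervals["start"] >= self.intervals["end"]).any():
            bad = self.intervals[self.intervals["start"] >= self.intervals["end"]].iloc[0]
            raise FormatError(f"interval with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}")
        self._trees = {}
        for chrom, sub in self.intervals.groupby("chrom"):
            tree = IntervalTree()
            for row in sub.itertuples(index=False):
                tree.addi(int(row.start), int(row.end), (row.feature, row.gene_id))
            self._trees[chrom] = tree

    def chroms(self):
        return set(self._trees)

    def overlaps(self, chrom: str, start: int, end: int):
        """All (feature, gene_id, overlap_bp) for features hit by [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        out = []
        for iv in tree.overlap(start, end):
            bp = min(end, iv.end) - max(start, iv.begin)
            out.append((iv.data[0], iv.data[1], bp))
        return out

    def query(self, chrom: str, pos: int) -> str:
        """Feature at a single 0-based position, precedence-resolved."""
        hits = self.overlaps(chrom, pos, pos + 1)
        return resolve_feature([(f, g, bp) for f, g, bp in hits])[0]


def resolve_feature(hits) -> tuple[str, Optional[str]]:
    """Resolve overlapping annotations to one (feature, gene_id).

    Precedence promoter > exon > intron is applied first (any exon
    overlap beats any intron overlap regardless of extent); among hits of
    the winning feature class, maximal overlap picks the gene.  No hits
    -> intergenic.
    """
    if not hits:
        return INTERGENIC, None
    rank = {f: i for i, f in enumerate(FEATURE_PRECEDENCE)}
    best = min(hits, key=lambda h: (rank.get(h[0], len(rank)), -h[2]))
    return best[0], best[1]


def read_gene_model(path, promoter_upstream: int = 2000, promoter_downstream: int = 500) -> GeneModel:
    """Read a BED-like gene model: chrom, start, end, feature, gene_id, strand.

    Coordinates are 0-based half-open (BED convention).  ``feature`` may be
    promoter/exon/intron (used verbatim) or transcript/gene (a promoter
    window is derived around the strand-aware TSS).
    """
    rows = []
    derived = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 columns, got {len(parts)}")
            chrom, start, end, feature, gene_id = parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4]
            strand = parts[5] if len(parts) > 5 else "+"
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            if feature in FEATURE_PRECEDENCE:
                rows.append((chrom, start, end, feature, gene_id, strand))
            elif feature in ("transcript", "gene"):
                if strand == "-":
                    tss = end  # half-open: TSS at `end` boundary
                    p_start, p_end = tss - promoter_downstream, tss + promoter_upstream
                else:
                    tss = start
                    p_start, p_end = tss - promoter_upstream, tss + promoter_downstream
                derived.append((chrom, max(0, p_start), max(1, p_end), "promoter", gene_id, strand))
            else:
                raise FormatError(f"{path}:{lineno}: unknown feature {feature!r}")
    df = pd.DataFrame(rows + derived, columns=["chrom", "start", "end", "feature", "gene_id", "strand"])
    return GeneModel(df)


# ---------------------------------------------------------------------------
# Reference methylation tracks (100-bp grids)

def read_reference_track(path, source: str) -> pd.DataFrame:
    """Read a 100-bp region methylation table: chrom, start, end, meth_percent."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "start", "end", "meth_percent"], header=None,
                     dtype={"chrom": str})
    first = df.iloc[0] if len(df) else None
    if first is not None and isinstance(first["start"], str):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.astype({"start": np.int64, "end": np.int64, "meth_percent": float})
    if ((df["meth_percent"] < 0) | (df["meth_percent"] > 100)).any():
        raise FormatError(f"{path}: meth_percent outside [0, 100]")
    df.insert(0, "source", source)
    return df


def write_reference_track(track: pd.DataFrame, path) -> None:
    track[["chrom", "start", "end", "meth_percent"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Tabular assay / litter inputs

LITTER_COLUMNS = ["dam_id", "diet", "corpora_lutea", "implantation_sites", "resorptions"]
EMBRYO_COLUMNS = ["dam_id", "embryo_id", "weight", "placenta_weight", "sex", "crown_rump", "malformed"]


def read_litter_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(LITTER_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_embryo_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EMBRYO_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["malformed"] = df["malformed"].astype(bool)
    return df


def read_luma_table(path) -> pd.DataFrame:
    """LUMA peak-ratio table: sample_id, diet, tissue, sex, and duplicate
    HpaII/EcoRI and MspI/EcoRI ratio columns (hpaii_ecori_1, hpaii_ecori_2,
    mspi_ecori_1, mspi_ecori_2) or single averaged columns."""
    df = pd.read_csv(path, sep="\t")
    if "hpaii_ecori" not in df.columns:
        dup_h = [c for c in df.columns if c.startswith("hpaii_ecori_")]
        dup_m = [c for c in df.columns if c.startswith("mspi_ecori_")]
        if not dup_h or not dup_m:
            raise FormatError(f"{path}: no HpaII/EcoRI or MspI/EcoRI ratio columns")
        df["hpaii_ecori"] = df[dup_h].mean(axis=1)
        df["mspi_ecori"] = df[dup_m].mean(axis=1)
    return df


def read_pyro_table(path) -> pd.DataFrame:
    """Pyrosequencing table: sample_id, gene, diet, tissue, sex, cpg1..cpgN percents."""
    df = pd.read_csv(path, sep="\t")
    cpg_cols = [c for c in df.columns if c.lower().startswith("cpg")]
    if not cpg_cols:
        raise FormatError(f"{path}: no per-CpG percent columns (cpg1..cpgN)")
    vals = df[cpg_cols]
    if ((vals < 0) | (vals > 100)).any().any():
        raise FormatError(f"{path}: CpG percent outside [0, 100]")
    df["mean_percent"] = vals.mean(axis=1)
    return df
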