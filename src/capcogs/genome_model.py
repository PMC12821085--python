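"""Coordinate backbone and file I/O.

All coordinates are 0-based, half-open ``[start, end)`` internally; BED files
pass through unchanged and promoter tables give the TSS as a 0-based position.
Restriction fragment maps must tile each chromosome contiguously — gaps or
overlaps are format errors, not something this module repairs.

Distance between a bait and an other end is midpoint-to-midpoint, the same
axis on which the CHiCAGO distance function is tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """An input file violates its documented contract."""


class DomainError(ValueError):
    """An operation was asked for outside its domain (e.g. a trans pair)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval; ``strand`` is '+', '-' or '.'."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


#: GRCh38 MHC interval excluded from GWAS gene scoring (extreme LD). The
#: printed 1-based inclusive span 6:28510120-33480577 converted to 0-based
#: half-open.
MHC_GRCH38 = GenomicInterval("6", 28510119, 33480577)


@dataclass(frozen=True)
class Promoter:
    """One transcription start site of a gene and its hosting fragment."""

    gene_id: str
    chrom: str
    tss: int
    fragment_id: int
    baited: bool


@dataclass(frozen=True)
class Peak:
    """An epigenomic peak (ATAC or H3K27ac) carrying a read count."""

    interval: GenomicInterval
    assay: str
    read_count: float

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")


class FragmentMap:
    """Ordered restriction fragments tiling each chromosome.

    Fragment IDs are the integer row index in genome order (chromosome name
    sorted lexicographically, then start).  The map is the coordinate backbone
    for every other feature in the toolkit.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise FormatError(f"fragment table needs columns {sorted(required)}")
        df = df[["chrom", "start", "end"]].copy()
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise FormatError(f"empty/inverted fragment {bad.chrom}:{bad.start}-{bad.end}")
        # contiguity per chromosome
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            mism = np.nonzero(starts[1:] != ends[:-1])[0]
            if mism.size:
                i = mism[0]
                kind = "gap" if starts[i + 1] > ends[i] else "overlap"
                raise FormatError(
                    f"{kind} between fragments {chrom}:{starts[i]}-{ends[i]} "
                    f"and {chrom}:{starts[i+1]}-{ends[i+1]}"
                )
        df["fragment_id"] = np.arange(len(df))
        self.df = df
        self._by_chrom = {
            chrom: (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["fragment_id"].to_numpy(),
            )
            for chrom, sub in df.groupby("chrom", sort=False)
        }

    def __len__(self) -> int:
        return len(self.df)

    @property
    def median_length(self) -> float:
        return float(np.median(self.df["end"] - self.df["start"]))

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def fragment_id_range(self, chrom: str) -> tuple[int, int]:
        """First and last fragment ID on a chromosome (inclusive)."""
        _, _, ids = self._chrom(chrom)
        return int(ids[0]), int(ids[-1])

    def chrom_bounds(self, chrom: str) -> tuple[int, int]:
        starts, ends, _ = self._chrom(chrom)
        return int(starts[0]), int(ends[-1])

    def _chrom(self, chrom: str):
        try:
            return self._by_chrom[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in fragment map") from None

    def fragment(self, fragment_id: int) -> GenomicInterval:
        row = self.df.iloc[int(fragment_id)]
        return GenomicInterval(row.chrom, int(row.start), int(row.end))

    def fragment_chrom(self, fragment_id: int) -> str:
        return self.df.iloc[int(fragment_id)].chrom

    def fragment_midpoint(self, fragment_id: int) -> float:
        row = self.df.iloc[int(fragment_id)]
        return 0.5 * (row.start + row.end)

    def locate(self, chrom: str, pos: int) -> int:
        """Fragment ID containing position ``pos`` (0-based)."""
        starts, ends, ids = self._chrom(chrom)
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= ends[i]:
            raise KeyError(f"position {chrom}:{pos} outside fragment map")
        return int(ids[i])

    def overlapping(self, interval: GenomicInterval) -> list[int]:
        """IDs of all fragments overlapping ``interval`` by >= 1 bp."""
        starts, ends, ids = self._chrom(interval.chrom)
        lo = int(np.searchsorted(ends, interval.start, side="right"))
        hi = int(np.searchsorted(starts, interval.end, side="left"))
        return [int(x) for x in ids[lo:hi]]

    def flanking(self, fragment_id: int) -> list[int]:
        """The fragments immediately adjacent on the same chromosome."""
        chrom = self.fragment_chrom(fragment_id)
        _, _, ids = self._chrom(chrom)
        out = []
        if fragment_id - 1 >= ids[0]:
            out.append(fragment_id - 1)
        if fragment_id + 1 <= ids[-1]:
            out.append(fragment_id + 1)
        return out


def assign_to_fragments(
    intervals: list[GenomicInterval], fragmap: FragmentMap
) -> dict[GenomicInterval, list[int]]:
    """Map each interval to every fragment it overlaps by >= 1 bp."""
    return {iv: fragmap.overlapping(iv) for iv in intervals}


@dataclass
class ChicagoParams:
    """CHiCAGO model parameters consumed by ABCC imputation.

    ``f_d`` is tabulated on knots ``(distance bp, expected normalised count)``
    and evaluated by piecewise-linear interpolation in log-log space; beyond
    the outermost knots the terminal slope is extrapolated.  The CHiCAGO fit
    is close to log-log linear, so this representation loses little.
    """

    bmean: float
    s_i: dict[int, float]
    s_j: dict[int, float]
    f_knots: np.ndarray = field(default=None)  # shape (k, 2), distance ascending

    def __post_init__(self) -> None:
        if self.bmean <= 0:
            raise ValueError("bmean must be > 0")
        for name, table in (("s_i", self.s_i), ("s_j", self.s_j)):
            if any(v <= 0 for v in table.values()):
                raise ValueError(f"all {name} scaling factors must be > 0")
        if self.f_knots is not None:
            k = np.asarray(self.f_knots, dtype=float)
            if k.ndim != 2 or k.shape[1] != 2 or k.shape[0] < 2:
                raise ValueError("f_knots must be (k>=2, 2)")
            if (np.diff(k[:, 0]) <= 0).any():
                raise ValueError("f_knots distances must be strictly increasing")
            if (np.diff(k[:, 1]) > 0).any():
                raise ValueError("f(d) must be non-increasing in distance")
            if (k <= 0).any():
                raise ValueError("f_knots must be positive for log-log interpolation")
            self.f_knots = k
            self._logd = np.log(k[:, 0])
            self._logf = np.log(k[:, 1])

    def f(self, distance: float) -> float:
        """Expected normalised count at ``distance`` bp (log-log interpolation)."""
        if self.f_knots is None:
            raise ValueError("no distance function tabulated")
        if distance <= 0:
            raise ValueError("distance must be positive")
        ld = np.log(distance)
        logd, logf = self._logd, self._logf
        if ld <= logd[0]:
            slope = (logf[1] - logf[0]) / (logd[1] - logd[0])
            return float(np.exp(logf[0] + slope * (ld - logd[0])))
        if ld >= logd[-1]:
            slope = (logf[-1] - logf[-2]) / (logd[-1] - logd[-2])
            return float(np.exp(logf[-1] + slope * (ld - logd[-1])))
        return float(np.exp(np.interp(ld, logd, logf)))


# ---------------------------------------------------------------------------
# interaction table
# ---------------------------------------------------------------------------

_INTERACTION_COLUMNS = [
    "bait_id", "oe_chrom", "oe_start", "oe_end", "oe_frags",
    "n_obs", "raw_reads", "score", "distance", "trans", "resolution",
]


class InteractionTable:
    """Bait <-> other-end records in CHiCAGO-normalised count space.

    Backed by a DataFrame with one row per record; ``oe_frags`` is the tuple
    of constituent other-end fragment IDs (one element at fragment
    resolution).  ``distance`` is midpoint-to-midpoint in bp and NaN for
    trans-chromosomal rows, which are retained here and filtered downstream.
    """

    def __init__(self, df: pd.DataFrame, fragmap: FragmentMap):
        missing = [c for c in _INTERACTION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"interaction table missing columns {missing}")
        if (df["n_obs"] < 0).any() or (df["raw_reads"] < 0).any():
            raise FormatError("negative counts in interaction table")
        self.df = df.reset_index(drop=True)
        self.fragmap = fragmap

    def __len__(self) -> int:
        return len(self.df)

    def cis(self) -> "InteractionTable":
        return InteractionTable(self.df[~self.df["trans"]].copy(), self.fragmap)

    def pair_index(self) -> dict[tuple[int, int], int]:
        """(bait_id, oe fragment_id) -> row position; expands binned rows."""
        out: dict[tuple[int, int], int] = {}
        for pos, (bait, frags) in enumerate(
            zip(self.df["bait_id"], self.df["oe_frags"])
        ):
            for f in frags:
                out.setdefault((int(bait), int(f)), pos)
        return out


def _oe_span(frag_ids: list[int], fragmap: FragmentMap) -> tuple[str, int, int]:
    ivs = [fragmap.fragment(f) for f in frag_ids]
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) > 1:
        raise FormatError(f"other-end fragments {frag_ids} span chromosomes")
    return ivs[0].chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs)


def build_interactions(
    records: list[dict], fragmap: FragmentMap, resolution: str | None = None
) -> InteractionTable:
    """Assemble an InteractionTable from dicts with keys
    ``bait_id, oe_frags, n_obs, raw_reads, score`` (and optional
    ``resolution``)."""
    rows = []
    for rec in records:
        bait = int(rec["bait_id"])
        frags = tuple(int(f) for f in rec["oe_frags"])
        if not frags:
            raise FormatError("record with empty other end")
        for f in list(frags) + [bait]:
            if not (0 <= f < len(fragmap)):
                raise FormatError(f"unknown fragment ID {f}")
        chrom, start, end = _oe_span(list(frags), fragmap)
        bait_iv = fragmap.fragment(bait)
        trans = bait_iv.chrom != chrom
        dist = np.nan if trans else abs(bait_iv.midpoint - 0.5 * (start + end))
        res = rec.get("resolution") or resolution
        if res is None:
            res = "fragment" if len(frags) == 1 else "bin5kb"
        rows.append(
            {
                "bait_id": bait,
                "oe_chrom": chrom,
                "oe_start": start,
                "oe_end": end,
                "oe_frags": frags,
                "n_obs": float(rec["n_obs"]),
                "raw_reads": int(rec.get("raw_reads", 0)),
                "score": float(rec["score"]),
                "distance": dist,
                "trans": trans,
                "resolution": res,
            }
        )
    df = pd.DataFrame(rows, columns=_INTERACTION_COLUMNS)
    return InteractionTable(df, fragmap)


def read_interactions(
    path, fragmap: FragmentMap, resolution: str | None = None
) -> InteractionTable:
    """Read a CHiCAGO-style interaction TSV.

    Expected header columns: ``baitID``, ``otherEndID`` (comma-separated
    fragment IDs for binned other ends), ``N`` (normalised count),
    ``N.reads`` (raw reads, optional), ``score``.  Resolution is taken from a
    ``resolution`` column if present, else from the argument, else inferred
    from the other-end width.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        return InteractionTable(
            pd.DataFrame(columns=_INTERACTION_COLUMNS), fragmap
        )
    needed = {"baitID", "otherEndID", "N", "score"}
    if not needed.issubset(df.columns):
        raise FormatError(f"interaction TSV needs columns {sorted(needed)}")
    reads = df["N.reads"] if "N.reads" in df.columns else pd.Series(0, index=df.index)
    records = []
    for i in df.index:
        rec = {
            "bait_id": int(df.at[i, "baitID"]),
            "oe_frags": [int(x) for x in str(df.at[i, "otherEndID"]).split(",")],
            "n_obs": float(df.at[i, "N"]),
            "raw_reads": int(reads[i]),
            "score": float(df.at[i, "score"]),
        }
        if "resolution" in df.columns:
            rec["resolution"] = df.at[i, "resolution"]
        records.append(rec)
    return build_interactions(records, fragmap, resolution=resolution)


def write_interactions(table: InteractionTable, path) -> None:
    df = table.df.copy()
    df["otherEndID"] = [",".join(str(f) for f in t) for t in df["oe_frags"]]
    out = df.rename(columns={"bait_id": "baitID", "n_obs": "N", "raw_reads": "N.reads"})
    out = out[["baitID", "otherEndID", "N", "N.reads", "score", "resolution"]]
    out.to_csv(path, sep="\t", index=False)


def merge_consensus(
    frag_res: InteractionTable, binned: InteractionTable
) -> pd.DataFrame:
    """Consensus of fragment-resolution and 5 kb-binned interactions.

    Both tables are expanded to (bait, other-end fragment) grain and
    set-unioned; a pair seen at both resolutions is recorded once with
    provenance ``both`` and the elementwise maximum of count/score.  Returns a
    DataFrame with columns ``bait_id, oe_frag, n_obs, raw_reads, score,
    distance, trans, provenance``.
    """
    if frag_res.fragmap is not binned.fragmap and not frag_res.fragmap.df.equals(
        binned.fragmap.df
    ):
        raise FormatError("consensus merge requires a shared fragment map")
    fragmap = frag_res.fragmap

    def expand(table: InteractionTable) -> dict[tuple[int, int], dict]:
        out: dict[tuple[int, int], dict] = {}
        for row in table.df.itertuples(index=False):
            for f in row.oe_frags:
                key = (int(row.bait_id), int(f))
                prev = out.get(key)
                if prev is None or row.score > prev["score"]:
                    out[key] = {
                        "n_obs": float(row.n_obs),
                        "raw_reads": int(row.raw_reads),
                        "score": float(row.score),
                        "trans": bool(row.trans),
                    }
        return out

    a = expand(frag_res)
    b = expand(binned)
    rows = []
    for key in sorted(set(a) | set(b)):
        bait, oe = key
        ra, rb = a.get(key), b.get(key)
        src = "both" if (ra and rb) else ("fragment" if ra else "bin")
        best = ra if (rb is None or (ra and ra["score"] >= rb["score"])) else rb
        merged = dict(best)
        if ra and rb:
            merged["n_obs"] = max(ra["n_obs"], rb["n_obs"])
            merged["raw_reads"] = max(ra["raw_reads"], rb["raw_reads"])
            merged["score"] = max(ra["score"], rb["score"])
        bait_iv = fragmap.fragment(bait)
        trans = merged["trans"]
        dist = (
            np.nan
            if trans
            else abs(bait_iv.midpoint - fragmap.fragment_midpoint(oe))
        )
        rows.append(
            {
                "bait_id": bait,
                "oe_frag": oe,
                "n_obs": merged["n_obs"],
                "raw_reads": merged["raw_reads"],
                "score": merged["score"],
                "distance": dist,
                "trans": trans,
                "provenance": src,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bait_id", "oe_frag", "n_obs", "raw_reads", "score",
            "distance", "trans", "provenance",
        ],
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fragment_map(path) -> FragmentMap:
    """Read a restriction fragment BED (>=3 columns, sortable)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    if df.empty:
        raise FormatError(f"empty fragment BED: {path}")
    return FragmentMap(df)


def write_fragment_map(fragmap: FragmentMap, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fragmap.df[["chrom", "start", "end"]].to_csv(
            fh, sep="\t", index=False, header=False
        )


def read_promoters(path, fragmap: FragmentMap | None = None) -> list[Promoter]:
    """Read a promoter TSV with columns gene_id, chrom, tss, baited
    (and optionally fragment_id, resolved from the map when absent)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"gene_id", "chrom", "tss", "baited"}
    if not needed.issubset(df.columns):
        raise FormatError(f"promoter TSV needs columns {sorted(needed)}")
    out = []
    for row in df.itertuples(index=False):
        if "fragment_id" in df.columns and not pd.isna(row.fragment_id):
            fid = int(row.fragment_id)
        elif fragmap is not None:
            fid = fragmap.locate(str(row.chrom), int(row.tss))
        else:
            raise FormatError("fragment_id column or a fragment map required")
        out.append(
            Promoter(str(row.gene_id), str(row.chrom), int(row.tss), fid,
                     bool(row.baited))
        )
    return out


def write_promoters(promoters: list[Promoter], path, header: str | None = None) -> None:
    df = pd.DataFrame(
        [
            {"gene_id": p.gene_id, "chrom": p.chrom, "tss": p.tss,
             "fragment_id": p.fragment_id, "baited": p.baited}
            for p in promoters
        ]
    ).sort_values(["gene_id", "tss"])
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_peaks(path, assay: str) -> list[Peak]:
    """Read a peak BED with a 4th read-count column."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "count"],
    )
    return [
        Peak(GenomicInterval(str(r.chrom), int(r.start), int(r.end)), assay,
             float(r.count))
        for r in df.itertuples(index=False)
    ]


def write_peaks(peaks: list[Peak], path, header: str | None = None) -> None:
    rows = sorted(
        (p.interval.chrom, p.interval.start, p.interval.end, p.read_count)
        for p in peaks
    )
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for chrom, start, end, count in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{count:.6g}\n")


def read_chicago_params(path) -> ChicagoParams:
    """Read model parameters from YAML: ``bmean``, ``s_i``, ``s_j``, ``f_d``
    (list of [distance, value] knots)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ChicagoParams(
        bmean=float(raw["bmean"]),
        s_i={int(k): float(v) for k, v in raw["s_i"].items()},
        s_j={int(k): float(v) for k, v in raw["s_j"].items()},
        f_knots=np.asarray(raw["f_d"], dtype=float) if raw.get("f_d") else None,
    )


def write_chicago_params(params: ChicagoParams, path) -> None:
    payload = {
        "bmean": float(params.bmean),
        "s_i": {int(k): float(v) for k, v in params.s_i.items()},
        "s_j": {int(k): float(v) for k, v in params.s_j.items()},
        "f_d": [[float(d), float(v)] for d, v in params.f_knots]
        if params.f_knots is not None
        else None,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def read_intervals_bed(path) -> list[GenomicInterval]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    return [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]
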