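"""Activity-by-Captured-Contact (ABCC) enhancer-gene scoring.

The ABC score of an element-gene pair is the product of the element's
Activity (geometric mean of ATAC and H3K27ac read counts) and its Contact
with the gene promoter, normalised by the sum of such products over all
candidate elements within a 5 Mb window of the TSS:

    ABC(E, G) = A_E * C_EG / sum_e A_e * C_eG

Contact here is imputed in CHiCAGO-normalised count space rather than taken
from KR-normalised Hi-C.  For a baited promoter the contact is
``max(N_obs, N_exp)`` where ``N_exp = Bmean / (s_i * s_j)`` is the Brownian
collision floor transported into normalised-count space through the bait and
other-end scaling factors; contacts are never allowed below that floor.  For
promoters absent from the capture design (or QC-failed, i.e. lacking a bait
scaling factor) the contact is read off the CHiCAGO distance function f(d),
capped at f(median fragment length) for elements less than one fragment from
the bait, where f is steep and would otherwise overwhelm longer-range
contacts.

The deployed score cutoff for calling enhancer-gene pairs is 0.023, selected
by maximising the Pearson correlation between the per-gene sum of ABC
numerators above the cutoff and gene expression (see ``select_cutoff``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from capcogs.genome_model import (
    ChicagoParams,
    DomainError,
    FragmentMap,
    GenomicInterval,
    InteractionTable,
    Peak,
    Promoter,
)

#: Deployed ABCC score cutoff for calling enhancer-gene pairs.
DEFAULT_CALL_CUTOFF = 0.023

#: Window around the TSS within which candidate elements are scored.
DEFAULT_WINDOW_BP = 5_000_000.0


@dataclass(frozen=True)
class CandidateElement:
    """A candidate regulatory element: merged peak interval plus activity."""

    interval: GenomicInterval
    fragment_ids: tuple[int, ...]
    atac_count: float
    h3k27ac_count: float
    activity: float

    @property
    def key(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"


def element_activity(atac_count: float, h3k27ac_count: float,
                     pseudocount: float = 0.0) -> float:
    """Geometric mean of the two assay read counts.

    With the default zero pseudocount a zero in either assay zeroes the
    element; a positive pseudocount is subtracted back out after the mean and
    the result clipped at 0.
    """
    if atac_count < 0 or h3k27ac_count < 0:
        raise ValueError("read counts must be >= 0")
    g = math.sqrt((atac_count + pseudocount) * (h3k27ac_count + pseudocount))
    return max(g - pseudocount, 0.0)


def build_candidate_elements(
    atac_peaks: list[Peak],
    h3k27ac_peaks: list[Peak],
    fragmap: FragmentMap,
    pseudocount: float = 0.0,
) -> list[CandidateElement]:
    """Candidate element universe: union of ATAC and H3K27ac peaks, with
    overlapping peaks merged into one element.

    Per-assay counts of a merged element are the sums over its member peaks;
    activity is their geometric mean.  Exclusion of a gene's own promoter
    fragment happens at scoring time, per gene.
    """
    peaks = sorted(
        atac_peaks + h3k27ac_peaks,
        key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end),
    )
    elements: list[CandidateElement] = []
    cluster: list[Peak] = []

    def flush() -> None:
        if not cluster:
            return
        chrom = cluster[0].interval.chrom
        start = min(p.interval.start for p in cluster)
        end = max(p.interval.end for p in cluster)
        atac = sum(p.read_count for p in cluster if p.assay == "ATAC")
        k27 = sum(p.read_count for p in cluster if p.assay == "H3K27ac")
        iv = GenomicInterval(chrom, start, end)
        elements.append(
            CandidateElement(
                interval=iv,
                fragment_ids=tuple(fragmap.overlapping(iv)),
                atac_count=atac,
                h3k27ac_count=k27,
                activity=element_activity(atac, k27, pseudocount),
            )
        )

    for peak in peaks:
        if cluster and (
            peak.interval.chrom == cluster[0].interval.chrom
            and peak.interval.start < max(p.interval.end for p in cluster)
        ):
            cluster.append(peak)
        else:
            flush()
            cluster = [peak]
    flush()
    return elements


def expected_contact(
    bait_id: int, oe_id: int, params: ChicagoParams, *, divide_both: bool = True
) -> float:
    """Brownian-floor expected normalised count for a fragment pair.

    ``divide_both`` selects ``Bmean / (s_i * s_j)``; the alternative reading
    ``(Bmean / s_i) * s_j`` is available behind the flag.
    """
    try:
        si = params.s_i[bait_id]
    except KeyError:
        raise KeyError(f"no bait scaling factor for fragment {bait_id}") from None
    try:
        sj = params.s_j[oe_id]
    except KeyError:
        raise KeyError(f"no other-end scaling factor for fragment {oe_id}") from None
    if divide_both:
        return params.bmean / (si * sj)
    return params.bmean / si * sj


def pair_counts_from_interactions(table: InteractionTable) -> dict[tuple[int, int], float]:
    """(bait_id, other-end fragment) -> observed normalised count."""
    out: dict[tuple[int, int], float] = {}
    for row in table.df.itertuples(index=False):
        for f in row.oe_frags:
            key = (int(row.bait_id), int(f))
            out[key] = max(out.get(key, 0.0), float(row.n_obs))
    return out


def pair_counts_from_consensus(consensus: pd.DataFrame) -> dict[tuple[int, int], float]:
    out: dict[tuple[int, int], float] = {}
    for row in consensus.itertuples(index=False):
        key = (int(row.bait_id), int(row.oe_frag))
        out[key] = max(out.get(key, 0.0), float(row.n_obs))
    return out


def impute_contact(
    promoter: Promoter,
    element: CandidateElement,
    pair_counts: dict[tuple[int, int], float],
    params: ChicagoParams,
    fragmap: FragmentMap,
    *,
    divide_both: bool = True,
) -> float:
    """Imputed contact frequency between a promoter and a candidate element.

    Baited promoters with a bait scaling factor use
    ``max(N_obs, N_exp)`` per element fragment (``N_obs = 0`` for pairs
    absent from the interaction table) and return the maximum over the
    element's fragments.  Unbaited or QC-failed promoters fall back to the
    distance function, with the short-range cap ``f(median fragment length)``
    when the element touches the bait fragment or one adjacent to it.
    """
    if element.interval.chrom != promoter.chrom:
        raise DomainError(
            f"trans pair: promoter on {promoter.chrom}, "
            f"element on {element.interval.chrom}"
        )
    bait = promoter.fragment_id
    if promoter.baited and bait in params.s_i:
        best = 0.0
        for frag in element.fragment_ids:
            n_obs = pair_counts.get((bait, frag), 0.0)
            n_exp = expected_contact(bait, frag, params, divide_both=divide_both)
            best = max(best, max(n_obs, n_exp))
        return best
    # fallback: distance function with short-range cap
    near = set(element.fragment_ids) & ({bait} | set(fragmap.flanking(bait)))
    if near:
        return params.f(fragmap.median_length)
    distance = abs(fragmap.fragment_midpoint(bait) - element.interval.midpoint)
    return params.f(distance)


def abc_scores(
    gene_id: str,
    promoter: Promoter,
    elements: list[CandidateElement],
    pair_counts: dict[tuple[int, int], float],
    params: ChicagoParams,
    fragmap: FragmentMap,
    *,
    window_bp: float = DEFAULT_WINDOW_BP,
    exclude_promoter_fragment: bool = True,
    divide_both: bool = True,
) -> pd.DataFrame:
    """ABC scores for one gene promoter over its 5 Mb window.

    Window membership is by element midpoint within ``window_bp / 2`` of the
    TSS on the same chromosome.  Elements whose fragments include the gene's
    own baited promoter fragment are excluded from the gene's candidate list
    (mirroring the original ABC's promoter exclusion) unless
    ``exclude_promoter_fragment`` is False.  Returns one row per in-window
    element with columns ``gene_id, element, activity, contact, numerator,
    abc_score, zero_denominator``; per-gene scores sum to 1 whenever any
    numerator is positive.
    """
    half = window_bp / 2.0
    rows = []
    for el in elements:
        if el.interval.chrom != promoter.chrom:
            continue
        if abs(el.interval.midpoint - promoter.tss) > half:
            continue
        if exclude_promoter_fragment and promoter.fragment_id in el.fragment_ids:
            continue
        contact = impute_contact(
            promoter, el, pair_counts, params, fragmap, divide_both=divide_both
        )
        rows.append(
            {
                "gene_id": gene_id,
                "element": el.key,
                "chrom": el.interval.chrom,
                "start": el.interval.start,
                "end": el.interval.end,
                "fragment_ids": el.fragment_ids,
                "activity": el.activity,
                "contact": contact,
                "numerator": el.activity * contact,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "element", "chrom", "start", "end", "fragment_ids",
            "activity", "contact", "numerator",
        ],
    )
    denom = df["numerator"].sum() if len(df) else 0.0
    if denom > 0:
        df["abc_score"] = df["numerator"] / denom
        df["zero_denominator"] = False
    else:
        df["abc_score"] = 0.0
        df["zero_denominator"] = True
    return df


def call_enhancer_pairs(pairs: pd.DataFrame,
                        cutoff: float = DEFAULT_CALL_CUTOFF) -> pd.DataFrame:
    """Pairs with ``abc_score >= cutoff``, sorted by gene then score
    descending."""
    called = pairs[pairs["abc_score"] >= cutoff].copy()
    return called.sort_values(
        ["gene_id", "abc_score"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)


def select_cutoff(
    pairs: pd.DataFrame,
    expression: dict[str, float],
    grid: np.ndarray,
) -> tuple[float, pd.DataFrame]:
    """Score cutoff maximising the correlation of per-gene retained ABC
    numerator mass with gene expression.

    For each candidate cutoff the per-gene statistic is the sum of
    numerators of elements scoring at or above it; the returned cutoff
    maximises the Pearson correlation of that statistic with expression over
    genes present in both tables (ties broken toward the smallest cutoff).
    Also returns the full correlation curve.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    genes = sorted(set(pairs["gene_id"]) & set(expression))
    if len(genes) < 20 and len(grid) > 1:
        raise ValueError(f"need >= 20 genes with expression, got {len(genes)}")
    expr = np.array([expression[g] for g in genes])
    if np.ptp(expr) == 0:
        raise ValueError("expression vector is constant; correlation undefined")
    curve = []
    for cut in grid:
        kept = pairs[pairs["abc_score"] >= cut]
        stat = kept.groupby("gene_id")["numerator"].sum()
        vec = np.array([stat.get(g, 0.0) for g in genes])
        r = np.nan if np.ptp(vec) == 0 else float(np.corrcoef(vec, expr)[0, 1])
        curve.append({"cutoff": float(cut), "pearson_r": r})
    curve_df = pd.DataFrame(curve)
    finite = curve_df.dropna(subset=["pearson_r"])
    if finite.empty:
        raise ValueError("correlation undefined at every cutoff")
    best = finite.loc[finite["pearson_r"].idxmax()]
    # idxmax returns the first maximum; grid is sorted ascending, so ties
    # already resolve to the smallest cutoff
    return float(best["cutoff"]), curve_df


def evaluate_pairs(
    predicted: set[tuple[str, str]],
    truth: dict[tuple[str, str], bool],
) -> tuple[float, float]:
    """Precision and recall of predicted (gene, element) pairs over a
    labelled universe; pairs outside the universe are ignored.

    Returns ``(precision, recall)``; precision is NaN when nothing in the
    universe was predicted.
    """
    if not truth:
        raise ValueError("empty truth set")
    labelled_pred = {p for p in predicted if p in truth}
    tp = sum(1 for p in labelled_pred if truth[p])
    positives = sum(1 for v in truth.values() if v)
    precision = tp / len(labelled_pred) if labelled_pred else float("nan")
    recall = tp / positives if positives else float("nan")
    return precision, recall
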