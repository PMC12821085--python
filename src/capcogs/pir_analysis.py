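"""Collapsed-PIR enrichment and alternative-promoter sharing.

Adjacent promoter-interacting regions (PIRs) of a gene are merged into
"collapsed PIRs" (cPIRs).  Enrichment of cPIRs for epigenomic features is
assessed against a transplantation null: each gene's whole cPIR set is
re-anchored, with every size and bait-relative offset preserved exactly, at
the baited fragment of a randomly drawn gene.  This preserves both each
PIR's distance from its bait and the spatial relationships between the
multiple PIRs of one gene — unlike per-PIR shuffles.  The fold enrichment is
the observed overlap proportion over the null mean, with a 95% CI from the
delta method on the log fold, propagating the binomial error of the observed
proportion and the Monte Carlo error of the null mean.

The sharing classifier labels each significant PIR of a gene with multiple
baited alternative promoters as fully shared (contacts all promoters at
CHiCAGO score >= 5), partially shared (a strict subset of more than one,
possible only with more than two promoters), shared (rescued by a lenient
score >= 3 contact of the PIR itself or of an adjacent fragment with another
promoter), or distinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from capcogs.genome_model import FragmentMap, GenomicInterval, Promoter

DEFAULT_N_PERM = 100

#: Sharing-classifier thresholds.
SHARING_SCORE = 5.0
SHARING_READS = 5
LENIENT_SCORE = 3.0


@dataclass(frozen=True)
class CollapsedPir:
    """A merged run of adjacent PIR fragments of one gene.

    Offsets are signed bp relative to the start of the gene's baited
    fragment, so the member interval is reconstructed exactly from any
    anchor position.
    """

    gene_id: str
    interval: GenomicInterval
    member_fragments: tuple[int, ...]
    offset_start: int
    offset_end: int

    @property
    def length(self) -> int:
        return self.offset_end - self.offset_start


def collapse_pirs(
    gene_id: str,
    pir_fragments: list[int],
    bait_fragment: int,
    fragmap: FragmentMap,
) -> list[CollapsedPir]:
    """Merge a gene's PIR fragments into cPIRs.

    Trans-chromosomal PIRs are dropped; overlapping or book-ended runs of
    fragments (consecutive IDs) merge into one cPIR.  Offsets are recorded
    relative to the bait fragment start.
    """
    bait_chrom = fragmap.fragment_chrom(bait_fragment)
    anchor = fragmap.fragment(bait_fragment).start
    cis = sorted(
        {f for f in pir_fragments if fragmap.fragment_chrom(f) == bait_chrom}
    )
    out: list[CollapsedPir] = []
    run: list[int] = []

    def flush() -> None:
        if not run:
            return
        start = fragmap.fragment(run[0]).start
        end = fragmap.fragment(run[-1]).end
        out.append(
            CollapsedPir(
                gene_id=gene_id,
                interval=GenomicInterval(bait_chrom, start, end),
                member_fragments=tuple(run),
                offset_start=start - anchor,
                offset_end=end - anchor,
            )
        )

    for f in cis:
        if run and f == run[-1] + 1:
            run.append(f)
        else:
            flush()
            run = [f]
    flush()
    return out


class _FeatureIndex:
    """Per-chromosome sorted feature starts with a prefix-max of ends, for
    O(log n) any-overlap queries."""

    def __init__(self, features: list[GenomicInterval]):
        self._idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in features:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            starts = np.array([p[0] for p in pairs])
            ends = np.maximum.accumulate(np.array([p[1] for p in pairs]))
            self._idx[chrom] = (starts, ends)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        entry = self._idx.get(chrom)
        if entry is None:
            return False
        starts, prefix_max_end = entry
        k = int(np.searchsorted(starts, end, side="left"))
        return k > 0 and prefix_max_end[k - 1] > start


def overlap_proportion(
    intervals: list[tuple[str, int, int]], features: list[GenomicInterval]
) -> float:
    """Proportion of intervals overlapping at least one feature by >= 1 bp."""
    if not intervals:
        raise ValueError("no intervals")
    index = _FeatureIndex(features)
    hits = sum(1 for chrom, s, e in intervals if index.overlaps(chrom, s, e))
    return hits / len(intervals)


def transplant_permutation(
    cpir_sets: dict[str, list[CollapsedPir]],
    anchors: dict[str, tuple[str, int]],
    features: list[GenomicInterval],
    fragmap: FragmentMap,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    collect_placements: bool = False,
) -> tuple[np.ndarray, int] | tuple[np.ndarray, int, list[dict]]:
    """Null overlap proportions from cPIR transplantation.

    ``anchors`` maps every universe gene to its baited-fragment anchor
    ``(chrom, start)``.  Each permutation re-anchors every gene's full cPIR
    set at a uniformly drawn target gene's anchor, preserving all sizes and
    offsets exactly; a draw whose transplanted set exceeds the target
    chromosome bounds is re-drawn (count returned).  Returns the per-
    permutation overlap proportions against ``features`` and the re-draw
    count; with ``collect_placements`` also a per-permutation mapping
    ``gene -> (anchor, [(chrom, start, end), ...])`` of where each cPIR
    landed.
    """
    genes = sorted(cpir_sets)
    universe = sorted(anchors)
    if len(universe) < 2:
        raise ValueError("gene universe must contain at least 2 genes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    index = _FeatureIndex(features)
    bounds = {c: fragmap.chrom_bounds(c) for c in fragmap.chromosomes}

    props = np.empty(n_perm)
    redraws = 0
    placements: list[dict] = []
    for perm in range(n_perm):
        hits = 0
        total = 0
        perm_placed: dict[str, tuple[int, list]] = {}
        for gene in genes:
            cpirs = cpir_sets[gene]
            if not cpirs:
                continue
            while True:
                target = universe[int(rng.integers(len(universe)))]
                chrom, anchor = anchors[target]
                lo, hi = bounds[chrom]
                placed = [
                    (chrom, anchor + c.offset_start, anchor + c.offset_end)
                    for c in cpirs
                ]
                if all(lo <= s and e <= hi for _, s, e in placed):
                    break
                redraws += 1
            perm_placed[gene] = (anchor, placed)
            for chrom_, s, e in placed:
                total += 1
                hits += index.overlaps(chrom_, s, e)
        props[perm] = hits / total if total else np.nan
        if collect_placements:
            placements.append(perm_placed)
    if collect_placements:
        return props, redraws, placements
    return props, redraws


@dataclass(frozen=True)
class EnrichmentResult:
    observed_prop: float
    null_mean: float
    null_sd: float
    fold: float
    ci95: tuple[float, float]
    n_perm: int
    n_cpirs: int


def feature_enrichment(
    cpirs: list[CollapsedPir],
    features: list[GenomicInterval],
    null_props: np.ndarray,
) -> EnrichmentResult:
    """Observed/expected overlap enrichment with a delta-method 95% CI.

    Fold = observed proportion / null mean.  The CI combines the binomial
    variance of the observed proportion with the standard error of the null
    mean on the log-fold scale:
    ``exp(log fold +/- 1.96 sqrt(Var(p_obs)/p_obs^2 + Var(null_mean)/null_mean^2))``.
    """
    null_props = np.asarray(null_props, dtype=float)
    n_perm = null_props.size
    null_mean = float(null_props.mean())
    null_sd = float(null_props.std(ddof=1)) if n_perm > 1 else 0.0
    if null_mean == 0:
        raise ValueError("null mean overlap proportion is 0; fold undefined")
    intervals = [(c.interval.chrom, c.interval.start, c.interval.end) for c in cpirs]
    p_obs = overlap_proportion(intervals, features)
    fold = p_obs / null_mean
    n = len(intervals)
    if p_obs > 0:
        var_obs = p_obs * (1.0 - p_obs) / n
        var_null_mean = null_sd ** 2 / n_perm
        half = 1.96 * np.sqrt(
            var_obs / p_obs ** 2 + var_null_mean / null_mean ** 2
        )
        ci = (float(fold * np.exp(-half)), float(fold * np.exp(half)))
    else:
        ci = (float("nan"), float("nan"))
    return EnrichmentResult(
        observed_prop=p_obs,
        null_mean=null_mean,
        null_sd=null_sd,
        fold=fold,
        ci95=ci,
        n_perm=n_perm,
        n_cpirs=n,
    )


def classify_pir_sharing(
    gene_id: str,
    promoters: list[Promoter],
    contacts: pd.DataFrame,
    fragmap: FragmentMap,
    *,
    score_min: float = SHARING_SCORE,
    reads_min: int = SHARING_READS,
    lenient_score: float = LENIENT_SCORE,
) -> pd.DataFrame:
    """Label each significant PIR of a multi-promoter gene.

    ``contacts`` is a fragment-grain table with columns ``bait_id, oe_frag,
    score, raw_reads``.  The gene qualifies when it has more than one baited
    promoter, each with at least one contact at score >= 5 and >= 5 reads.
    Per significant PIR (score >= 5 with any qualifying promoter):
    ``fully_shared`` if it contacts all qualifying promoters at score >= 5;
    ``partially_shared`` for a strict subset of more than one;
    otherwise ``shared`` when rescued by a lenient (score >= 3) contact of
    the PIR or either flanking fragment with another promoter, else
    ``distinct``.
    """
    baited = [p for p in promoters if p.gene_id == gene_id and p.baited]
    scores: dict[tuple[int, int], float] = {}
    reads: dict[tuple[int, int], int] = {}
    for row in contacts.itertuples(index=False):
        key = (int(row.bait_id), int(row.oe_frag))
        scores[key] = max(scores.get(key, 0.0), float(row.score))
        reads[key] = max(reads.get(key, 0), int(row.raw_reads))

    def qualifies(p: Promoter) -> bool:
        return any(
            bait == p.fragment_id and sc >= score_min
            and reads.get((bait, oe), 0) >= reads_min
            for (bait, oe), sc in scores.items()
        )

    qual = [p for p in baited if qualifies(p)]
    if len(qual) < 2:
        raise ValueError(
            f"gene {gene_id} does not qualify: needs >1 baited promoter with "
            f"a score>={score_min}, reads>={reads_min} interaction"
        )
    prom_frags = sorted({p.fragment_id for p in qual})

    pir_universe = sorted(
        {
            oe
            for (bait, oe), sc in scores.items()
            if bait in prom_frags and sc >= score_min
        }
    )
    rows = []
    for pir in pir_universe:
        strong = {pf for pf in prom_frags if scores.get((pf, pir), 0.0) >= score_min}
        if strong == set(prom_frags):
            label = "fully_shared"
        elif len(strong) > 1:
            label = "partially_shared"
        else:
            others = set(prom_frags) - strong
            lenient_self = any(
                scores.get((pf, pir), 0.0) >= lenient_score for pf in others
            )
            lenient_adj = any(
                scores.get((pf, adj), 0.0) >= lenient_score
                for adj in fragmap.flanking(pir)
                for pf in others
            )
            label = "shared" if (lenient_self or lenient_adj) else "distinct"
        rows.append({"gene_id": gene_id, "pir_fragment": pir, "label": label})
    return pd.DataFrame(rows, columns=["gene_id", "pir_fragment", "label"])
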