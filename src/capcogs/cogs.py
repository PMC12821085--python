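"""COGS and multiCOGS gene prioritisation.

A gene's feature set is the union, over its promoters, of four categories of
genomic loci: its coding SNP positions, the promoter-proximal window (TSS
fragment +/- 5 restriction fragments), other ends of significant promoter
contacts (CHiCAGO score >= 5) anchored at the gene's baited promoters, and
ABCC enhancers (ABC score >= 0.04) paired with the gene.  Promoters
contribute the proximal window whether or not they were baited in the
capture design.

For one fine-mapped signal, the gene's score is the posterior mass falling
in its features: the sum of PIPs over the *unique* variants covered by any
feature (a variant in two overlapping features counts once — summation over
a union keeps the score a probability).  multiCOGS combines the per-signal
scores across all (LD block, credible set) signals as the probability that
at least one signal is linked to the gene:

    multiCOGS(gene) = 1 - prod_signals (1 - score_signal)

Standard COGS is the same machinery restricted to one (single-causal)
signal per block.  Variants in the MHC are excluded before scoring; genes
with multiCOGS > 0.5 are flagged as prioritised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from capcogs.finemap import Signal
from capcogs.genome_model import FragmentMap, GenomicInterval, MHC_GRCH38, Promoter

CATEGORIES = ("coding", "promoter_proximal", "pchic_pir", "abcc_enhancer")

#: CHiCAGO score threshold for a PIR to enter the feature set.
CHICAGO_SCORE_MIN = 5.0

#: ABCC score threshold for an enhancer to enter the feature set.
ABCC_COGS_MIN = 0.04

#: Fragments either side of the TSS fragment forming the proximal window.
PROXIMAL_FRAGMENTS = 5

#: Prioritisation threshold on the combined gene score (strict >).
DEFAULT_PRIORITISE_CUTOFF = 0.5


@dataclass(frozen=True)
class GeneFeatureSet:
    """Per-gene union of scoring features, labelled by category."""

    gene_id: str
    coding_positions: frozenset[tuple[str, int]]
    fragments: dict[str, frozenset[int]]  # keys: the three fragment categories

    def category_fragments(self, category: str) -> frozenset[int]:
        return self.fragments.get(category, frozenset())

    def covers(
        self,
        chrom: str,
        pos: int,
        fragmap: FragmentMap,
        categories: tuple[str, ...] = CATEGORIES,
    ) -> bool:
        """True if the variant position falls in any feature of the listed
        categories."""
        if "coding" in categories and (chrom, pos) in self.coding_positions:
            return True
        frag_cats = [c for c in categories if c != "coding"]
        if not frag_cats:
            return False
        try:
            fid = fragmap.locate(chrom, pos)
        except KeyError:
            return False
        return any(fid in self.fragments.get(c, frozenset()) for c in frag_cats)


def build_gene_features(
    gene_id: str,
    promoters: list[Promoter],
    fragmap: FragmentMap,
    consensus: pd.DataFrame,
    abcc_pairs: pd.DataFrame,
    coding_map: dict[str, set[tuple[str, int]]],
    *,
    chicago_score_min: float = CHICAGO_SCORE_MIN,
    abcc_score_min: float = ABCC_COGS_MIN,
    proximal_fragments: int = PROXIMAL_FRAGMENTS,
) -> GeneFeatureSet:
    """Assemble the four-category feature set for one gene.

    Unbaited promoters contribute coding SNPs and the proximal window only;
    PIRs come from consensus contacts anchored at baited promoter fragments
    with score at or above the CHiCAGO threshold (trans contacts excluded);
    ABCC enhancers from pairs for this gene at or above the ABC threshold.
    """
    mine = [p for p in promoters if p.gene_id == gene_id]
    if not mine:
        raise ValueError(f"gene {gene_id} has no annotated promoter/TSS")

    proximal: set[int] = set()
    pirs: set[int] = set()
    for prom in mine:
        lo, hi = fragmap.fragment_id_range(prom.chrom)
        tss_frag = prom.fragment_id
        proximal.update(
            range(max(lo, tss_frag - proximal_fragments),
                  min(hi, tss_frag + proximal_fragments) + 1)
        )
        if prom.baited and len(consensus):
            hits = consensus[
                (consensus["bait_id"] == tss_frag)
                & (consensus["score"] >= chicago_score_min)
                & (~consensus["trans"])
            ]
            pirs.update(int(f) for f in hits["oe_frag"])

    enhancers: set[int] = set()
    if len(abcc_pairs):
        hits = abcc_pairs[
            (abcc_pairs["gene_id"] == gene_id)
            & (abcc_pairs["abc_score"] >= abcc_score_min)
        ]
        for frags in hits["fragment_ids"]:
            enhancers.update(int(f) for f in frags)

    return GeneFeatureSet(
        gene_id=gene_id,
        coding_positions=frozenset(coding_map.get(gene_id, set())),
        fragments={
            "promoter_proximal": frozenset(proximal),
            "pchic_pir": frozenset(pirs),
            "abcc_enhancer": frozenset(enhancers),
        },
    )


def score_signal_for_gene(
    features: GeneFeatureSet,
    signal: Signal,
    variant_positions: dict[str, tuple[str, int]],
    fragmap: FragmentMap,
    *,
    categories: tuple[str, ...] = CATEGORIES,
    on_missing: str = "drop",
) -> float:
    """Posterior mass of one signal landing in a gene's features.

    Sums PIP over the unique variants covered by any feature (union
    semantics), clipped to [0, 1].  Variants with unknown positions are
    dropped with a warning by default (``on_missing='error'`` raises).
    """
    total = 0.0
    for variant, pip in signal.pip.items():
        loc = variant_positions.get(variant)
        if loc is None:
            if on_missing == "error":
                raise KeyError(f"unknown position for variant {variant}")
            warnings.warn(f"dropping variant {variant}: unknown position",
                          stacklevel=2)
            continue
        if features.covers(loc[0], loc[1], fragmap, categories):
            total += pip
    return min(max(total, 0.0), 1.0)


def multicogs_score(per_signal_scores: list[float]) -> float:
    """Probability that at least one signal is linked:
    ``1 - prod(1 - s)``; 0 for no signals."""
    prod = 1.0
    for s in per_signal_scores:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"per-signal score outside [0,1]: {s}")
        prod *= 1.0 - s
    return 1.0 - prod


def standard_cogs_score(
    features: GeneFeatureSet,
    signals: list[Signal],
    variant_positions: dict[str, tuple[str, int]],
    fragmap: FragmentMap,
) -> float:
    """COGS score from single-causal signals: one signal per LD block,
    combined with the same at-least-one-signal rule."""
    blocks = [s.block_id for s in signals]
    if len(blocks) != len(set(blocks)):
        raise ValueError("standard COGS requires exactly one signal per block")
    scores = [
        score_signal_for_gene(features, sig, variant_positions, fragmap)
        for sig in signals
    ]
    return multicogs_score(scores)


def decompose_by_category(
    features: GeneFeatureSet,
    signals: list[Signal],
    variant_positions: dict[str, tuple[str, int]],
    fragmap: FragmentMap,
) -> dict[str, float]:
    """multiCOGS re-run with features restricted to one category at a time."""
    out = {}
    for cat in CATEGORIES:
        scores = [
            score_signal_for_gene(
                features, sig, variant_positions, fragmap, categories=(cat,)
            )
            for sig in signals
        ]
        out[cat] = multicogs_score(scores)
    return out


def exclude_region(
    signals: list[Signal],
    variant_positions: dict[str, tuple[str, int]],
    regions: tuple[GenomicInterval, ...] = (MHC_GRCH38,),
) -> list[Signal]:
    """Remove variants inside the given regions (default: the GRCh38 MHC)
    before scoring.  Positions are 0-based; a variant on a region boundary
    follows half-open arithmetic.  Signals left empty are dropped."""
    if not regions:
        return list(signals)
    out = []
    for sig in signals:
        kept = {
            v: p
            for v, p in sig.pip.items()
            if not any(
                region.contains(*variant_positions[v])
                for region in regions
                if v in variant_positions
            )
        }
        if kept:
            out.append(Signal(sig.block_id, sig.credset_id, kept))
    return out


def score_genes(
    feature_sets: list[GeneFeatureSet],
    signals: list[Signal],
    variant_positions: dict[str, tuple[str, int]],
    fragmap: FragmentMap,
) -> pd.DataFrame:
    """Full multiCOGS table: per-gene combined score, per-category
    decomposition and the number of signals with positive overlap."""
    rows = []
    for feats in feature_sets:
        per_signal = [
            score_signal_for_gene(feats, sig, variant_positions, fragmap)
            for sig in signals
        ]
        cats = decompose_by_category(feats, signals, variant_positions, fragmap)
        rows.append(
            {
                "gene_id": feats.gene_id,
                "multicogs": multicogs_score(per_signal),
                **{f"score_{c}": cats[c] for c in CATEGORIES},
                "n_signals_contributing": sum(1 for s in per_signal if s > 0),
            }
        )
    return pd.DataFrame(rows)


def prioritise(
    gene_scores: pd.DataFrame,
    cutoff: float = DEFAULT_PRIORITISE_CUTOFF,
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """Rank genes by multiCOGS score (descending; ties broken by gene_id)
    and flag those above the cutoff (strict > by default)."""
    df = gene_scores.copy()
    if df.empty:
        df["prioritised"] = pd.Series(dtype=bool)
        return df
    op = np.greater if strict else np.greater_equal
    df["prioritised"] = op(df["multicogs"], cutoff)
    df = df.sort_values(
        ["multicogs", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
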