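"""Seeded synthetic-data generators with planted ground truth.

Every input the toolkit consumes can be generated here: a restriction
fragment map with a stated median fragment length, CHiCAGO-style interaction
tables with power-law distance decay plus planted true contacts, ATAC and
H3K27ac peak tracks with strong peaks at planted enhancers, AR(1)-LD GWAS
blocks with planted causal variants, credible sets concentrating posterior
mass on them, and gene expression coupled to planted enhancer activity.

All randomness flows from one integer seed through a single
``numpy.random.Generator``.  The planted objects are recorded in a
:class:`Truth` record so recovery tests can check the pipeline end to end.

Scales are desk-sized by design (defaults: 3 chromosomes x 2,000 fragments,
200 genes, 20 LD blocks x 100 variants) — small enough for a full
genome -> contacts -> GWAS -> ABCC -> multiCOGS run in seconds, large enough
for distance decay, LD structure and score normalisation to behave
non-trivially.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from capcogs import abcc as abcc_mod
from capcogs.genome_model import (
    ChicagoParams,
    FragmentMap,
    GenomicInterval,
    InteractionTable,
    Peak,
    Promoter,
    build_interactions,
    write_chicago_params,
    write_fragment_map,
    write_interactions,
    write_peaks,
    write_promoters,
)
from capcogs.finemap import Signal, p_from_z, write_signals


@dataclass
class Genome:
    fragmap: FragmentMap
    promoters: list[Promoter]
    gene_ids: list[str]


@dataclass
class Truth:
    """Planted ground truth emitted alongside every synthetic fixture."""

    planted_enhancer_pairs: list[dict] = field(default_factory=list)
    planted_causals: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_enhancer_pairs": self.planted_enhancer_pairs,
                    "planted_causals": self.planted_causals,
                    "params": self.params,
                },
                fh,
                indent=2,
            )


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_genome(
    seed: int | np.random.Generator,
    n_chrom: int = 3,
    n_frag: int = 2000,
    median_len: int = 1500,
    n_genes: int = 200,
    baited_frac: float = 0.9,
) -> Genome:
    """Fragment map tiling ``n_chrom`` chromosomes with ``n_frag`` fragments
    each (lognormal lengths, median ~= ``median_len``), plus genes with 1-3
    alternative TSSs; ~90% of promoters are baited.

    Gene base fragments are spaced at least 10 fragments apart so promoters
    of different genes never share a fragment.
    """
    if n_frag < 20:
        raise ValueError("need at least 20 fragments per chromosome")
    rng = _rng(seed)
    rows = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        lengths = np.maximum(
            rng.lognormal(mean=np.log(median_len), sigma=0.55, size=n_frag), 100
        ).astype(int)
        ends = np.cumsum(lengths)
        starts = ends - lengths
        rows.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
        )
    fragmap = FragmentMap(pd.concat(rows, ignore_index=True))

    # candidate base fragments: spaced grid, edges avoided
    candidates = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        lo, hi = fragmap.fragment_id_range(chrom)
        candidates.extend(range(lo + 10, hi - 10, 10))
    if n_genes > len(candidates):
        raise ValueError(f"cannot place {n_genes} genes on {len(candidates)} slots")
    base = rng.choice(len(candidates), size=n_genes, replace=False)
    base_frags = sorted(candidates[i] for i in base)

    promoters = []
    gene_ids = []
    for g, bf in enumerate(base_frags):
        gene = f"G{g:04d}"
        gene_ids.append(gene)
        n_tss = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
        for k in range(n_tss):
            fid = bf + 2 * k  # alternative promoters a couple of fragments apart
            iv = fragmap.fragment(fid)
            tss = int(rng.integers(iv.start, iv.end))
            promoters.append(
                Promoter(gene, iv.chrom, tss, fid,
                         baited=bool(rng.random() < baited_frac))
            )
    return Genome(fragmap=fragmap, promoters=promoters, gene_ids=gene_ids)


# ---------------------------------------------------------------------------
# CHiCAGO-style interactions
# ---------------------------------------------------------------------------

def _poisson_score(raw: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """CHiCAGO-like significance score: -log10 Poisson upper tail of the raw
    count given its background mean."""
    sf = sps.poisson.sf(raw - 1, mu)
    return -np.log10(np.maximum(sf, 1e-300))


def make_chicago_data(
    genome: Genome,
    seed: int | np.random.Generator,
    bmean: float = 5.0,
    decay_exponent: float = 1.0,
    f0: float = 20.0,
    planted_contacts: list[tuple[str, int, int]] = (),
    fold_boost: float = 15.0,
    n_background_per_bait: int = 30,
    nb_dispersion: float = 10.0,
    trans_fraction: float = 0.01,
) -> tuple[InteractionTable, InteractionTable, ChicagoParams, Truth]:
    """Interaction tables (fragment-level and 5 kb-binned) plus model
    parameters, with planted true contacts.

    The distance function is a power law ``f(d) = f0 (d / median_len)^-a``
    tabulated on a log grid; per-fragment scaling factors are lognormal; raw
    background counts are negative binomial around
    ``(f(d) + bmean) * s_i * s_j`` and normalised back by the scaling
    factors.  Planted contacts — ``(gene_id, bait_fragment, oe_fragment)``
    triples — receive a ``fold_boost`` on the background mean and are
    guaranteed a score above 5 by construction (raw count raised to the
    Poisson 1e-6 tail where sampling fell short).
    """
    rng = _rng(seed)
    fragmap = genome.fragmap
    med = fragmap.median_length

    n = len(fragmap)
    s_all_i = dict(enumerate(rng.lognormal(0.0, 0.2, n)))
    s_all_j = dict(enumerate(rng.lognormal(0.0, 0.2, n)))
    d_grid = np.geomspace(200, 5e6, 30)
    f_vals = f0 * (d_grid / med) ** (-decay_exponent)
    params = ChicagoParams(
        bmean=bmean, s_i=s_all_i, s_j=s_all_j,
        f_knots=np.column_stack([d_grid, f_vals]),
    )

    baited_frags = sorted({p.fragment_id for p in genome.promoters if p.baited})
    planted_keys = {(b, o) for _, b, o in planted_contacts}

    records = []

    def emit(bait: int, oe: int, boost: float, force_significant: bool) -> None:
        bait_iv = fragmap.fragment(bait)
        oe_mid = fragmap.fragment_midpoint(oe)
        trans = fragmap.fragment_chrom(oe) != bait_iv.chrom
        d = max(abs(bait_iv.midpoint - oe_mid), med)
        fd = 0.05 if trans else params.f(d)
        si, sj = s_all_i[bait], s_all_j[oe]
        mu_bg = (fd + bmean) * si * sj
        mu = mu_bg * boost
        raw = rng.negative_binomial(
            nb_dispersion, nb_dispersion / (nb_dispersion + mu)
        )
        if force_significant:
            floor = int(sps.poisson.isf(1e-6, mu_bg)) + 1
            raw = max(raw, floor)
        if raw == 0:
            return
        score = float(_poisson_score(np.array([raw]), np.array([mu_bg]))[0])
        records.append(
            {
                "bait_id": bait,
                "oe_frags": [oe],
                "n_obs": raw / (si * sj),
                "raw_reads": int(raw),
                "score": round(score, 3),
                "resolution": "fragment",
            }
        )

    for bait in baited_frags:
        chrom = fragmap.fragment_chrom(bait)
        lo, hi = fragmap.fragment_id_range(chrom)
        for _ in range(n_background_per_bait):
            if rng.random() < trans_fraction and len(fragmap.chromosomes) > 1:
                others = [c for c in fragmap.chromosomes if c != chrom]
                oc = others[int(rng.integers(len(others)))]
                olo, ohi = fragmap.fragment_id_range(oc)
                oe = int(rng.integers(olo, ohi + 1))
            else:
                offset = int(np.exp(rng.uniform(np.log(2), np.log(400))))
                oe = bait + offset * (1 if rng.random() < 0.5 else -1)
                oe = min(max(oe, lo), hi)
                if oe == bait:
                    continue
            if (bait, oe) in planted_keys:
                continue
            emit(bait, oe, 1.0, False)

    for _, bait, oe in planted_contacts:
        emit(bait, oe, fold_boost, True)

    frag_table = build_interactions(records, fragmap, resolution="fragment")

    # binned companion table: planted contacts re-emitted as ~5 kb bins
    # (other-end fragment +/- 1) plus a thinned slice of the background
    bin_records = []
    for rec in records:
        oe = rec["oe_frags"][0]
        planted = (rec["bait_id"], oe) in planted_keys
        if not planted and rng.random() > 0.2:
            continue
        chrom = fragmap.fragment_chrom(oe)
        lo, hi = fragmap.fragment_id_range(chrom)
        frags = [f for f in (oe - 1, oe, oe + 1) if lo <= f <= hi]
        bin_records.append(
            {
                "bait_id": rec["bait_id"],
                "oe_frags": frags,
                "n_obs": rec["n_obs"],
                "raw_reads": rec["raw_reads"],
                "score": rec["score"],
                "resolution": "bin5kb",
            }
        )
    bin_table = build_interactions(bin_records, fragmap, resolution="bin5kb")

    truth = Truth(
        planted_enhancer_pairs=[
            {"gene_id": g, "bait_fragment": b, "oe_fragment": o}
            for g, b, o in planted_contacts
        ],
        params={
            "bmean": bmean, "decay_exponent": decay_exponent,
            "fold_boost": fold_boost,
        },
    )
    return frag_table, bin_table, params, truth


def make_peaks(
    genome: Genome,
    seed: int | np.random.Generator,
    planted_elements: list[GenomicInterval] = (),
    n_background: int = 600,
    paired_fraction: float = 0.6,
    planted_count: float = 20.0,
    background_count_mean: float = 15.0,
) -> tuple[list[Peak], list[Peak]]:
    """ATAC and H3K27ac peak tracks.

    Each planted element gets a strong peak in both assays (counts lognormal
    around ``planted_count``).  ``n_background`` random locations (width
    300-1,500 bp, exponential counts) carry peaks in both assays with
    probability ``paired_fraction`` — these are the active background
    elements with non-zero geometric-mean activity — and in one random assay
    otherwise.
    """
    rng = _rng(seed)
    fragmap = genome.fragmap
    atac: list[Peak] = []
    k27: list[Peak] = []
    for iv in planted_elements:
        for assay, bucket in (("ATAC", atac), ("H3K27ac", k27)):
            count = float(rng.lognormal(np.log(planted_count), 0.2))
            bucket.append(Peak(iv, assay, count))
    for _ in range(n_background):
        chrom = fragmap.chromosomes[int(rng.integers(len(fragmap.chromosomes)))]
        lo, hi = fragmap.chrom_bounds(chrom)
        width = int(rng.integers(300, 1500))
        start = int(rng.integers(lo, hi - width))
        iv = GenomicInterval(chrom, start, start + width)
        if rng.random() < paired_fraction:
            buckets = [("ATAC", atac), ("H3K27ac", k27)]
        elif rng.random() < 0.5:
            buckets = [("ATAC", atac)]
        else:
            buckets = [("H3K27ac", k27)]
        for assay, bucket in buckets:
            count = float(rng.exponential(background_count_mean)) + 1.0
            bucket.append(Peak(iv, assay, count))
    return atac, k27


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def make_blocks(genome: Genome, n_blocks: int = 20) -> pd.DataFrame:
    """Non-overlapping LD blocks covering the genome (equal spans per
    chromosome, round-robin allocation)."""
    chroms = genome.fragmap.chromosomes
    per = [n_blocks // len(chroms)] * len(chroms)
    for i in range(n_blocks % len(chroms)):
        per[i] += 1
    rows = []
    b = 0
    for chrom, k in zip(chroms, per):
        lo, hi = genome.fragmap.chrom_bounds(chrom)
        edges = np.linspace(lo, hi, k + 1).astype(int)
        for i in range(k):
            rows.append(
                {"chrom": chrom, "start": int(edges[i]), "end": int(edges[i + 1]),
                 "block_id": f"B{b:03d}"}
            )
            b += 1
    return pd.DataFrame(rows)


def ar1_corr(n: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix ``R[i, j] = rho^|i - j|``."""
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def make_gwas(
    genome: Genome,
    blocks: pd.DataFrame,
    seed: int | np.random.Generator,
    planted_causals: list[dict] = (),
    n_variants: int = 100,
    rho: float = 0.9,
    noncentrality: float = 7.0,
    pip_mass: float = 0.95,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], list[Signal], Truth]:
    """Per-block summary statistics under AR(1) LD with planted causals.

    Each planted causal is a dict with keys ``chrom``, ``pos`` and
    ``target_gene`` (and optional ``category``); the nearest generated
    variant in the containing block is moved onto ``pos`` and given
    non-centrality ``noncentrality``: z ~ MVN(R @ lambda, R).  p-values are
    two-sided normal tails.  A SuSiE-like credible-set list is emitted with
    exactly ``pip_mass`` on each planted variant (a one-variant 95% credible
    set, as produced for near-certain signals).

    Returns ``(stats, ld_by_block, credible_sets, truth)``.
    """
    rng = _rng(seed)
    stats_rows = []
    ld: dict[str, np.ndarray] = {}
    credsets: list[Signal] = []
    truth = Truth(params={"rho": rho, "noncentrality": noncentrality,
                          "pip_mass": pip_mass, "n_variants": n_variants})

    planted_by_block: dict[str, list[dict]] = {}
    for pc in planted_causals:
        hit = blocks[
            (blocks["chrom"] == pc["chrom"])
            & (blocks["start"] <= pc["pos"])
            & (pc["pos"] < blocks["end"])
        ]
        if hit.empty:
            raise ValueError(f"planted causal at {pc['chrom']}:{pc['pos']} "
                             "falls outside every block")
        planted_by_block.setdefault(hit.iloc[0]["block_id"], []).append(pc)

    for row in blocks.itertuples(index=False):
        block_id = row.block_id
        pos = np.sort(rng.integers(row.start, row.end, size=n_variants))
        for pc in planted_by_block.get(block_id, []):
            i = int(np.argmin(np.abs(pos - pc["pos"])))
            pos[i] = pc["pos"]
        pos = np.sort(pos)
        lam = np.zeros(n_variants)
        causal_info = [
            (int(np.nonzero(pos == pc["pos"])[0][0]), pc)
            for pc in planted_by_block.get(block_id, [])
        ]
        for i, _ in causal_info:
            lam[i] = noncentrality

        R = ar1_corr(n_variants, rho)
        L = np.linalg.cholesky(R + 1e-10 * np.eye(n_variants))
        z = R @ lam + L @ rng.standard_normal(n_variants)
        p = p_from_z(z)
        variants = [f"{block_id}_v{i:03d}" for i in range(n_variants)]
        for i in range(n_variants):
            stats_rows.append(
                {
                    "variant": variants[i], "chrom": row.chrom, "pos": int(pos[i]),
                    "beta": float(z[i]), "se": 1.0, "z": float(z[i]),
                    "p": float(p[i]), "block_id": block_id,
                }
            )
        ld[block_id] = R
        for k, (i, pc) in enumerate(causal_info):
            credsets.append(
                Signal(block_id, f"cs{k + 1}", {variants[i]: pip_mass})
            )
            truth.planted_causals.append(
                {
                    "block_id": block_id, "variant": variants[i],
                    "chrom": row.chrom, "pos": int(pos[i]),
                    "target_gene": pc["target_gene"],
                    "category": pc.get("category", "pchic_pir"),
                }
            )
    return pd.DataFrame(stats_rows), ld, credsets, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def make_expression(
    abcc_pairs: pd.DataFrame,
    seed: int | np.random.Generator,
    cutoff: float = 0.02,
    noise_sd: float = 0.0,
) -> dict[str, float]:
    """Gene expression coupled to ABC numerators: per gene the sum of
    numerators of elements scoring at or above ``cutoff``, plus Gaussian
    noise."""
    rng = _rng(seed)
    kept = abcc_pairs[abcc_pairs["abc_score"] >= cutoff]
    base = kept.groupby("gene_id")["numerator"].sum()
    return {
        g: float(base.get(g, 0.0) + rng.normal(0.0, noise_sd))
        for g in abcc_pairs["gene_id"].unique()
    }


# ---------------------------------------------------------------------------
# full fixture
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """A complete in-memory synthetic dataset plus its planted truth."""

    seed: int
    genome: Genome
    frag_interactions: InteractionTable
    bin_interactions: InteractionTable
    params: ChicagoParams
    atac: list[Peak]
    k27: list[Peak]
    blocks: pd.DataFrame
    gwas_stats: pd.DataFrame
    ld: dict[str, np.ndarray]
    credible_sets: list[Signal]
    coding_map: dict[str, set[tuple[str, int]]]
    expression: dict[str, float]
    abcc_pairs: pd.DataFrame
    truth: Truth


def generate_fixture(
    seed: int,
    n_chrom: int = 3,
    n_frag: int = 2000,
    n_genes: int = 200,
    n_blocks: int = 20,
    n_variants: int = 100,
    n_planted: int = 8,
    enhancer_offset_frags: tuple[int, int] = (30, 80),
    expression_noise_sd: float = 0.0,
    plant_enhancer_peaks: bool = True,
) -> Fixture:
    """End-to-end synthetic dataset with planted enhancer-gene pairs and
    planted GWAS causal variants inside those enhancers.

    For each of ``n_planted`` genes (with a baited promoter), one enhancer
    fragment 30-80 fragments away receives a planted contact, strong ATAC and
    H3K27ac peaks, and a planted causal variant at its midpoint whose
    credible set carries pip mass 0.95 and targets that gene.

    With ``plant_enhancer_peaks=False`` the planted fragments receive
    contacts but no peaks, so each planted causal variant falls in the
    target gene's PIR and (with high probability) in no other gene's
    features — the configuration for exact-score recovery checks.
    """
    rng = np.random.default_rng(seed)
    genome = make_genome(rng, n_chrom=n_chrom, n_frag=n_frag, n_genes=n_genes)
    fragmap = genome.fragmap

    baited = [p for p in genome.promoters if p.baited]
    by_gene: dict[str, Promoter] = {}
    for p in baited:
        by_gene.setdefault(p.gene_id, p)
    planted_genes = sorted(by_gene)[:: max(1, len(by_gene) // n_planted)][:n_planted]

    planted_contacts = []
    planted_elements = []
    planted_causals = []
    all_prom_frags = {p.fragment_id for p in genome.promoters}
    for gene in planted_genes:
        prom = by_gene[gene]
        lo, hi = fragmap.fragment_id_range(prom.chrom)
        # keep the planted enhancer out of every promoter-proximal window
        # (TSS fragment +/- 5) so its causal variant is specific to the
        # planted contact
        for _ in range(100):
            off = int(rng.integers(*enhancer_offset_frags))
            enh = min(prom.fragment_id + off, hi - 1)
            if all(abs(enh - pf) > 6 for pf in all_prom_frags):
                break
        iv = fragmap.fragment(enh)
        planted_contacts.append((gene, prom.fragment_id, enh))
        planted_elements.append(iv)
        planted_causals.append(
            {"chrom": iv.chrom, "pos": int(iv.midpoint), "target_gene": gene}
        )

    frag_table, bin_table, params, contact_truth = make_chicago_data(
        genome, rng, planted_contacts=planted_contacts
    )
    atac, k27 = make_peaks(
        genome, rng,
        planted_elements=planted_elements if plant_enhancer_peaks else [],
    )
    blocks = make_blocks(genome, n_blocks=n_blocks)
    gwas_stats, ld, credsets, gwas_truth = make_gwas(
        genome, blocks, rng, planted_causals=planted_causals,
        n_variants=n_variants,
    )

    # a handful of coding SNPs on non-planted genes, for category coverage
    coding_map: dict[str, set[tuple[str, int]]] = {}
    others = [g for g in genome.gene_ids if g not in planted_genes]
    for gene in others[:5]:
        prom = next(p for p in genome.promoters if p.gene_id == gene)
        coding_map[gene] = {(prom.chrom, prom.tss + 10)}

    # ABCC pairs for all genes with a baited promoter
    elements = abcc_mod.build_candidate_elements(atac, k27, fragmap)
    pair_counts = abcc_mod.pair_counts_from_interactions(frag_table)
    pair_frames = []
    for gene, prom in sorted(by_gene.items()):
        pair_frames.append(
            abcc_mod.abc_scores(gene, prom, elements, pair_counts, params, fragmap)
        )
    abcc_pairs = pd.concat(pair_frames, ignore_index=True)

    expression = make_expression(abcc_pairs, rng, noise_sd=expression_noise_sd)

    truth = Truth(
        planted_enhancer_pairs=contact_truth.planted_enhancer_pairs,
        planted_causals=gwas_truth.planted_causals,
        params={
            "seed": seed,
            **contact_truth.params,
            **gwas_truth.params,
            "n_planted": n_planted,
        },
    )
    return Fixture(
        seed=seed, genome=genome, frag_interactions=frag_table,
        bin_interactions=bin_table, params=params, atac=atac, k27=k27,
        blocks=blocks, gwas_stats=gwas_stats, ld=ld, credible_sets=credsets,
        coding_map=coding_map, expression=expression, abcc_pairs=abcc_pairs,
        truth=truth,
    )


def write_fixture(fixture: Fixture, outdir) -> dict[str, str]:
    """Serialise a fixture to plain-text files; returns {name: path}."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed_note = f"seed={fixture.seed}"
    paths = {}

    def _p(name: str) -> Path:
        paths[name] = str(out / name)
        return out / name

    write_fragment_map(fixture.genome.fragmap, _p("fragments.bed"), header=seed_note)
    write_promoters(fixture.genome.promoters, _p("promoters.tsv"), header=seed_note)
    write_interactions(fixture.frag_interactions, _p("interactions_fragment.tsv"))
    write_interactions(fixture.bin_interactions, _p("interactions_bin5kb.tsv"))
    write_chicago_params(fixture.params, _p("chicago_params.yaml"))
    write_peaks(fixture.atac, _p("atac.bed"), header=seed_note)
    write_peaks(fixture.k27, _p("h3k27ac.bed"), header=seed_note)
    fixture.blocks.to_csv(_p("ld_blocks.tsv"), sep="\t", index=False)
    fixture.gwas_stats.to_csv(_p("gwas_stats.tsv"), sep="\t", index=False)
    write_signals(fixture.credible_sets, _p("credible_sets.tsv"), header=seed_note)
    with open(_p("coding_snps.tsv"), "w") as fh:
        fh.write("gene_id\tchrom\tpos\n")
        for gene, positions in sorted(fixture.coding_map.items()):
            for chrom, pos in sorted(positions):
                fh.write(f"{gene}\t{chrom}\t{pos}\n")
    with open(_p("expression.tsv"), "w") as fh:
        fh.write("gene_id\texpression\n")
        for gene in sorted(fixture.expression):
            fh.write(f"{gene}\t{fixture.expression[gene]:.6g}\n")
    fixture.abcc_pairs.drop(columns=["fragment_ids"]).to_csv(
        _p("abcc_pairs.tsv"), sep="\t", index=False
    )
    fixture.truth.to_json(_p("truth.json"))
    return paths
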