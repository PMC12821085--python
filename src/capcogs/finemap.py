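"""Per-block GWAS fine-mapping preparation.

GWAS summary statistics are partitioned into approximately independent LD
blocks.  Within each block, z-scores at untyped variants are imputed by the
conditional-mean Gaussian rule ``z_m = R_mo (R_oo + lambda I)^-1 z_o`` from
the block LD matrix R.  Blocks whose minimum (observed or imputed) p-value
falls below 1e-6 are routed to multivariate fine-mapping, which is an
external step (SuSiE); its per-signal credible sets and PIPs are ingested
from a TSV.  The remaining blocks get a single-causal-variant posterior via
Wakefield approximate Bayes factors:

    ABF_v = sqrt(V / (V + W)) * exp(z_v^2 W / (2 (V + W))),   V = se_v^2

normalised to posterior probabilities of association summing to 1 across the
block.  The prior effect variance W defaults to 0.04 (prior sd 0.2 on the
log-odds scale), the conventional choice for case-control traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Ridge regularisation for summary-statistic imputation.
DEFAULT_LAMBDA = 0.1

#: Wakefield prior variance on the effect size.
DEFAULT_PRIOR_W = 0.04

#: Blocks below this minimum p go to multivariate fine-mapping.
TRIAGE_P = 1e-6

_PIP_SUM_TOL = 1e-6


@dataclass
class Signal:
    """One fine-mapped association signal: a credible set's PIPs."""

    block_id: str
    credset_id: str
    pip: dict[str, float]

    def __post_init__(self) -> None:
        for variant, p in self.pip.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"pip for {variant} outside [0,1]: {p}")
        total = sum(self.pip.values())
        if total > 1.0 + _PIP_SUM_TOL:
            raise ValueError(
                f"pips for signal {self.block_id}/{self.credset_id} "
                f"sum to {total:.6f} > 1"
            )


def partition_into_blocks(
    stats: pd.DataFrame, blocks: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], int]:
    """Assign variants to the unique LD block containing their position.

    ``stats`` needs columns ``variant, chrom, pos`` (plus whatever statistic
    columns ride along); ``blocks`` needs ``chrom, start, end, block_id``
    with half-open, non-overlapping intervals.  Returns the per-block tables
    and the count of variants falling in no block (dropped).
    """
    for chrom, sub in blocks.sort_values(["chrom", "start"]).groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping LD blocks on {chrom}")
    out: dict[str, pd.DataFrame] = {}
    assigned = pd.Series(pd.NA, index=stats.index, dtype="object")
    for row in blocks.itertuples(index=False):
        mask = (
            (stats["chrom"].astype(str) == str(row.chrom))
            & (stats["pos"] >= row.start)
            & (stats["pos"] < row.end)
        )
        assigned[mask] = row.block_id
    dropped = int(assigned.isna().sum())
    for block_id in blocks["block_id"]:
        sub = stats[assigned == block_id]
        out[block_id] = sub.sort_values("pos").reset_index(drop=True)
    return out, dropped


def impute_z(
    R: np.ndarray,
    z_obs: np.ndarray,
    observed: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional-mean imputation of z-scores within one LD block.

    ``R`` is the full variant-by-variant correlation matrix, ``observed`` a
    boolean mask over its rows and ``z_obs`` the z-scores at the observed
    variants (in mask order).  Observed positions pass through unchanged.
    Returns ``(z_full, r2)`` where ``r2`` is the per-variant imputation
    quality ``diag(R_mo (R_oo + lam I)^-1 R_om)`` (set to 1 at observed
    positions).
    """
    R = np.asarray(R, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    z_obs = np.asarray(z_obs, dtype=float)
    if observed.sum() == 0:
        raise ValueError("need at least one observed variant")
    if z_obs.shape[0] != observed.sum():
        raise ValueError("z_obs length must match number of observed variants")
    n = R.shape[0]
    z_full = np.empty(n)
    r2 = np.ones(n)
    z_full[observed] = z_obs
    missing = ~observed
    if missing.any():
        R_oo = R[np.ix_(observed, observed)] + lam * np.eye(int(observed.sum()))
        R_mo = R[np.ix_(missing, observed)]
        try:
            coef = np.linalg.solve(R_oo, z_obs)
            weights = np.linalg.solve(R_oo, R_mo.T)  # (n_obs, n_miss)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular regularised LD matrix; use lambda > 0"
            ) from exc
        z_full[missing] = R_mo @ coef
        r2[missing] = np.einsum("ij,ji->i", R_mo, weights)
    return z_full, r2


def p_from_z(z: np.ndarray) -> np.ndarray:
    """Two-sided normal-tail p-values from z-scores."""
    return 2.0 * sps.norm.sf(np.abs(np.asarray(z, dtype=float)))


def triage_blocks(
    block_stats: dict[str, pd.DataFrame], p_threshold: float = TRIAGE_P
) -> tuple[list[str], list[str]]:
    """Split blocks into (multivariate fine-map set, single-causal fallback
    set) by whether the block's minimum p-value is below the threshold.

    Blocks with no variants or no p column content go to the fallback set.
    """
    finemap_set, fallback = [], []
    for block_id, sub in block_stats.items():
        pmin = sub["p"].min() if len(sub) and "p" in sub.columns else np.inf
        (finemap_set if pmin < p_threshold else fallback).append(block_id)
    return finemap_set, fallback


def single_causal_ppa(
    z: np.ndarray,
    se: np.ndarray | float,
    prior_w: float = DEFAULT_PRIOR_W,
) -> np.ndarray:
    """Single-causal-variant posteriors from Wakefield approximate Bayes
    factors; returns a vector summing to 1.

    Computed in log space: ``log ABF = 0.5 log(V/(V+W)) + z^2 W / (2(V+W))``
    followed by a softmax, so large z never overflow.
    """
    z = np.asarray(z, dtype=float)
    se = np.broadcast_to(np.asarray(se, dtype=float), z.shape)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    v = se ** 2
    if np.any(v <= 0):
        raise ValueError("standard errors must be positive")
    log_abf = 0.5 * np.log(v / (v + prior_w)) + z ** 2 * prior_w / (2.0 * (v + prior_w))
    log_abf -= log_abf.max()
    abf = np.exp(log_abf)
    return abf / abf.sum()


def single_causal_signal(
    block_id: str, variants: list[str], z: np.ndarray,
    se: np.ndarray | float, prior_w: float = DEFAULT_PRIOR_W,
) -> Signal:
    """Wrap the single-causal posterior of one block as a Signal with
    credset_id ``"single"``."""
    ppa = single_causal_ppa(z, se, prior_w)
    return Signal(block_id, "single", dict(zip(variants, (float(x) for x in ppa))))


def ingest_credible_sets(path) -> list[Signal]:
    """Read externally fine-mapped credible sets from a TSV with columns
    ``block_id, credset_id, variant, pip``; one Signal per (block,
    credset).  PIPs are authoritative: variants need not appear in the
    summary statistics."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip",
                     dtype={"block_id": str, "credset_id": str, "variant": str})
    needed = {"block_id", "credset_id", "variant", "pip"}
    if not needed.issubset(df.columns):
        raise ValueError(f"credible-set TSV needs columns {sorted(needed)}")
    dup = df.duplicated(subset=["block_id", "credset_id", "variant"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (signal, variant): {bad.block_id}/{bad.credset_id}/{bad.variant}"
        )
    signals = []
    for (block_id, credset_id), sub in df.groupby(
        ["block_id", "credset_id"], sort=True
    ):
        signals.append(
            Signal(str(block_id), str(credset_id),
                   dict(zip(sub["variant"], sub["pip"].astype(float))))
        )
    return signals


def write_signals(signals: list[Signal], path, header: str | None = None) -> None:
    """Write signals as a credible-set TSV; pips are written with full
    precision so a read-back is exact."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("block_id\tcredset_id\tvariant\tpip\n")
        for sig in signals:
            for variant in sorted(sig.pip):
                fh.write(
                    f"{sig.block_id}\t{sig.credset_id}\t{variant}\t"
                    f"{sig.pip[variant]!r}\n"
                )
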