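"""Bias-aware species richness and diversity measures.

Six measures per spatial unit (hexagonal cell or 5° band), per depth zone and
optionally per phylum: number of records, observed species S_obs, Hurlbert
rarefaction ES50 (expected species in a random draw of 50 individuals),
incidence-based Chao2, the Abundance-based Coverage Estimator (ACE), and the
Inverse Simpson effective species number.

Occurrence records are treated as individuals for the abundance-based
estimators, the standard practice when feeding occurrence counts to
abundance-based richness functions; see the methods note for the caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import geogrid
from .geogrid import HexGrid, assign_band, assign_cell, assign_depth_zone

__all__ = [
    "es_n", "chao2", "chao2_from_counts", "ace", "inverse_simpson",
    "rarefaction_curve", "DiversitySummary", "diversity_summary", "summarize",
]


def _check_counts(abund) -> np.ndarray:
    a = np.asarray(abund)
    if a.size == 0:
        raise ValueError("abundance vector is empty")
    if not np.all(np.isfinite(a)):
        raise ValueError("abundance counts must be finite")
    if np.any(a != np.floor(a)):
        raise ValueError("abundance counts must be integers")
    a = a.astype(np.int64)
    if np.any(a < 1):
        raise ValueError("abundance counts must be >= 1")
    return a


def _ln_choose(a, b):
    """log C(a, b) for a >= b >= 0 (array-safe)."""
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def es_n(abund, n: int = 50) -> float | None:
    """Hurlbert rarefaction: expected species in a random draw of ``n``.

    ES_n = sum_i [1 - C(N - N_i, n) / C(N, n)], the per-species probability
    of appearing at least once in a hypergeometric subsample of n of the N
    individuals.  Binomial ratios are evaluated in log space.  Returns None
    when N < n: a unit with fewer than n records is insufficiently sampled
    (the gap criterion) and has no ES_n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a = _check_counts(abund)
    N = int(a.sum())
    if N < n:
        return None
    incl = np.ones(a.shape, dtype=float)
    ok = (N - a) >= n          # C(N - N_i, n) = 0 when N - N_i < n
    if np.any(ok):
        lr = _ln_choose(N - a[ok], n) - _ln_choose(N, n)
        incl[ok] = 1.0 - np.exp(lr)
    return float(incl.sum())


def rarefaction_curve(abund, n_grid=None) -> pd.DataFrame:
    """ES_n for a grid of subsample sizes (defaults to 1..N)."""
    a = _check_counts(abund)
    N = int(a.sum())
    if n_grid is None:
        n_grid = np.arange(1, N + 1)
    return pd.DataFrame({"n": n_grid, "es": [es_n(a, int(n)) for n in n_grid]})


def chao2_from_counts(s_obs: int, q1: int, q2: int, m: int) -> float:
    """Bias-corrected Chao2 from incidence frequency counts.

    S_obs + ((m-1)/m) * q1*(q1-1) / (2*(q2+1)); the bias-corrected form is
    used always (never q1^2/(2 q2)) so the estimate is defined when q2 = 0.
    """
    if m < 1:
        raise ValueError("need at least one sample")
    return float(s_obs + (m - 1) / m * q1 * (q1 - 1) / (2.0 * (q2 + 1)))


def chao2(incidence) -> float:
    """Chao2 from a species x samples presence/absence matrix."""
    inc = np.asarray(incidence, dtype=bool)
    if inc.ndim != 2 or inc.shape[1] < 1:
        raise ValueError("incidence must be 2-D species x samples with m >= 1")
    freq = inc.sum(axis=1)
    present = freq > 0
    s_obs = int(present.sum())
    q1 = int(np.sum(freq == 1))
    q2 = int(np.sum(freq == 2))
    return chao2_from_counts(s_obs, q1, q2, inc.shape[1])


def _chao1_bc(a: np.ndarray) -> float:
    f1 = int(np.sum(a == 1))
    f2 = int(np.sum(a == 2))
    return float(a.size + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def ace(abund, rare_threshold: int = 10) -> float:
    """Abundance-based Coverage Estimator.

    Species are split at <= rare_threshold individuals.  With S_rare rare
    species holding N_rare individuals, F_k species of abundance k, and
    sample coverage C = 1 - F_1/N_rare:

        gamma^2 = max((S_rare/C) * sum k(k-1) F_k / (N_rare (N_rare-1)) - 1, 0)
        ACE     = S_abund + S_rare/C + (F_1/C) * gamma^2

    When every rare species is a singleton the coverage is zero and the
    bias-corrected Chao1 of the full vector is returned instead.
    """
    a = _check_counts(abund)
    rare = a[a <= rare_threshold]
    s_abund = int(np.sum(a > rare_threshold))
    s_rare = rare.size
    if s_rare == 0:
        return float(a.size)
    n_rare = int(rare.sum())
    f1 = int(np.sum(rare == 1))
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return _chao1_bc(a)
    ks = np.arange(1, rare_threshold + 1)
    fk = np.array([np.sum(rare == k) for k in ks])
    if n_rare > 1:
        gamma2 = max((s_rare / c_ace) * np.sum(ks * (ks - 1) * fk) / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    else:
        gamma2 = 0.0
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def inverse_simpson(abund) -> float:
    """Effective species number 1 / sum p_i^2 (weights abundant species)."""
    a = _check_counts(abund).astype(float)
    p = a / a.sum()
    return float(1.0 / np.sum(p ** 2))


# ---------------------------------------------------------------------------
# per-unit summaries

@dataclass
class DiversitySummary:
    n_records: int
    s_obs: int
    es50: float | None
    chao2: float
    ace: float
    inv_simpson: float


def _incidence_counts(sub: pd.DataFrame) -> tuple[int, int, int]:
    """(m, q1, q2) with samples = distinct sampling events.

    The incidence sample unit is a distinct (dataset_id, event_date,
    coordinates rounded to 0.1°) tuple — a deterministic proxy for a
    sampling event.
    """
    ev = pd.MultiIndex.from_arrays([
        sub["dataset_id"].astype(str),
        sub["event_date"].astype(str),
        np.round(sub["latitude"].astype(float), 1),
        np.round(sub["longitude"].astype(float), 1),
    ])
    df = pd.DataFrame({"species": sub["accepted_species"].to_numpy(), "event": ev.to_numpy()})
    freq = df.drop_duplicates().groupby("species").size()
    m = int(pd.unique(ev).size)
    return m, int((freq == 1).sum()), int((freq == 2).sum())


def diversity_summary(sub: pd.DataFrame, es_size: int = 50) -> DiversitySummary:
    """All six measures for one group of QC'd records."""
    counts = sub.groupby("accepted_species").size().to_numpy()
    m, q1, q2 = _incidence_counts(sub)
    return DiversitySummary(
        n_records=int(len(sub)),
        s_obs=int(counts.size),
        es50=es_n(counts, es_size),
        chao2=chao2_from_counts(counts.size, q1, q2, m),
        ace=ace(counts),
        inv_simpson=inverse_simpson(counts),
    )


def summarize(records: pd.DataFrame, grid: HexGrid | None = None, by: str = "cell",
              per_zone: bool = True, phylum_filter: str | None = None,
              es_size: int = 50) -> pd.DataFrame:
    """Diversity summary table per spatial unit.

    ``by``: "cell" (requires ``grid``) or "band".  With ``per_zone`` the
    records are additionally split by depth zone and records lacking depth
    (zone "unknown") are excluded, mirroring the exclusion of depth-less
    records from depth-specific analyses; without it all records pool into
    zone "all".  ``phylum_filter`` restricts to one phylum.
    """
    df = records.copy()
    if phylum_filter is not None:
        df = df[df["phylum"] == phylum_filter]
    if by == "cell":
        if grid is None:
            raise ValueError("by='cell' requires a grid")
        if len(df):
            df["unit"] = assign_cell(grid, df["latitude"].to_numpy(), df["longitude"].to_numpy())
        else:
            df["unit"] = pd.Series(dtype=int)
        unit_col = "cell_id"
    elif by == "band":
        df["unit"] = assign_band(df["latitude"].to_numpy()) if len(df) else pd.Series(dtype=int)
        unit_col = "band_index"
    else:
        raise ValueError("by must be 'cell' or 'band'")

    if per_zone:
        df["zone"] = assign_depth_zone(df["depth"].to_numpy()) if len(df) else pd.Series(dtype=object)
        df = df[df["zone"] != "unknown"]
    else:
        df["zone"] = "all"

    rows = []
    for (unit, zone), sub in df.groupby(["unit", "zone"], sort=True):
        s = diversity_summary(sub, es_size=es_size)
        rows.append({unit_col: unit, "depth_zone": zone, "n_records": s.n_records,
                     "s_obs": s.s_obs, "es50": np.nan if s.es50 is None else s.es50,
                     "chao2": s.chao2, "ace": s.ace, "inv_simpson": s.inv_simpson})
    cols = [unit_col, "depth_zone", "n_records", "s_obs", "es50", "chao2", "ace", "inv_simpson"]
    out = pd.DataFrame(rows, columns=cols)
    if phylum_filter is not None:
        out.insert(2, "phylum", phylum_filter)
    return out


def complete_cell_table(cell_summaries: pd.DataFrame, covariates: pd.DataFrame,
                        zones=("shallow", "mesopelagic", "deep")) -> pd.DataFrame:
    """Outer-join summaries onto the full (unit, zone) frame.

    Units with ocean area but no records get n_records = 0 and s_obs = 0 so
    that gap accounting sees them; estimator columns stay NaN.
    """
    unit_col = covariates.index.name or "cell_id"
    full = pd.MultiIndex.from_product([covariates.index, list(zones)],
                                      names=[unit_col, "depth_zone"]).to_frame(index=False)
    merged = full.merge(cell_summaries, on=[unit_col, "depth_zone"], how="left")
    merged["n_records"] = merged["n_records"].fillna(0).astype(int)
    merged["s_obs"] = merged["s_obs"].fillna(0).astype(int)
    return merged.merge(covariates.reset_index(), on=unit_col, how="left")
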