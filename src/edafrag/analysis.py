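"""Diagnostics for a finished run: funnel checks and blind model selection.

Given the model pool (and, for retrospective analyses, the native
structure), this module computes:

* per-window CA RMSD of every library fragment to the native structure, and
  its correlation with the learned selection probabilities -- a direct test
  of whether the distribution drifts toward native-like fragments;
* the probability-weighted mean fragment RMSD per window, comparable across
  iterations;
* energy / RMSD histograms per iteration (distribution shifts);
* near-native enrichment among the lowest-energy models;
* energy-driven blind selection: the "first" prediction is the single
  lowest-energy model, the "best" prediction is the lowest-RMSD model among
  the five lowest energies (native used only to score the choice, never to
  make it);
* pool quality summaries (mean RMSD of the best q-quantile of models).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .conformation import _as_ca, build_coords, ca_rmsd, measure_torsions
from .fragment_io import FragmentLibrary, FragmentWindow
from .sampler import ModelRecord, Pmf

__all__ = [
    "fragment_native_rmsd",
    "native_window_torsions",
    "probability_rmsd_correlation",
    "weighted_fragment_rmsd",
    "mean_weighted_fragment_rmsd",
    "near_native_enrichment",
    "BlindSelection",
    "blind_select",
    "first_prediction",
    "summarize_quality",
    "histogram_by_iteration",
    "pool_rmsds",
    "rank_by_energy",
]


def rank_by_energy(pool: list[ModelRecord]) -> list[ModelRecord]:
    """Pool sorted by ascending energy; energy ties broken by model_id."""
    return sorted(pool, key=lambda r: (r.energy, r.model_id))


def pool_rmsds(pool: list[ModelRecord], native) -> np.ndarray:
    native_ca = _as_ca(native)
    return np.array([ca_rmsd(r.conformation.ca, native_ca) for r in pool])


def native_window_torsions(native_coords: np.ndarray, start: int, length: int) -> np.ndarray:
    """Torsions measured from the native structure over one window.

    Dihedrals that are inert within an isolated segment build (phi of the
    first segment residue; psi/omega of the last) are filled with neutral
    values so the result can be rebuilt with ideal geometry.
    """
    torsions = measure_torsions(native_coords)
    seg = torsions[start - 1 : start - 1 + length].copy()
    seg[np.isnan(seg)] = 180.0
    return seg


def fragment_native_rmsd(
    library_or_windows, native
) -> dict[int, np.ndarray]:
    """Per window: CA RMSD (A) of each fragment to the native window.

    Each fragment's 9- (or 3-) residue backbone is built with ideal geometry
    from its torsions and superposed on the native CA atoms of the window.
    Returns {window_start: rmsd vector aligned to fragment indices}.
    """
    if isinstance(library_or_windows, FragmentLibrary):
        windows = library_or_windows.windows9
    else:
        windows = library_or_windows
    native_ca = _as_ca(native)
    n = len(native_ca)
    table: dict[int, np.ndarray] = {}
    for w in windows:
        length = w.length
        if w.start + length - 1 > n:
            raise ValueError(
                f"native structure (length {n}) does not cover window "
                f"{w.start}..{w.start + length - 1}"
            )
        target = native_ca[w.start - 1 : w.start - 1 + length]
        rmsds = np.empty(w.n_fragments)
        for j, frag in enumerate(w.fragments):
            seg_ca = build_coords(frag.torsions)[:, 1, :]
            rmsds[j] = ca_rmsd(seg_ca, target)
        table[w.start] = rmsds
    return table


def probability_rmsd_correlation(pmf: Pmf, rmsds: np.ndarray) -> float:
    """Pearson r between selection probabilities and fragment RMSDs.

    Returns NaN when either vector is constant (correlation undefined, e.g.
    a still-uniform window).
    """
    p = np.asarray(pmf.probs, dtype=float)
    r = np.asarray(rmsds, dtype=float)
    if len(p) != len(r):
        raise ValueError("probability and RMSD vectors differ in length")
    if len(p) < 3:
        raise ValueError("need at least 3 fragments for a correlation")
    if np.ptp(p) == 0 or np.ptp(r) == 0:
        return float("nan")
    return float(stats.pearsonr(p, r).statistic)


def weighted_fragment_rmsd(pmf: Pmf, rmsds: np.ndarray) -> float:
    """Probability-weighted mean fragment RMSD for one window."""
    r = np.asarray(rmsds, dtype=float)
    if len(r) != len(pmf.probs):
        raise ValueError("probability and RMSD vectors differ in length")
    return float(pmf.probs @ r)


def mean_weighted_fragment_rmsd(
    pmfs: list[Pmf], table: dict[int, np.ndarray]
) -> float:
    """Average of the per-window weighted fragment RMSD over all windows."""
    values = [weighted_fragment_rmsd(p, table[p.window_start]) for p in pmfs]
    return float(np.mean(values))


def near_native_enrichment(
    pool: list[ModelRecord],
    native,
    n_lowest: int = 100,
    cutoff: float = 3.0,
) -> float:
    """Percentage of the n_lowest lowest-energy models within cutoff (A)."""
    if native is None:
        raise ValueError("native structure required")
    if len(pool) < n_lowest:
        raise ValueError(f"pool size {len(pool)} < n_lowest {n_lowest}")
    chosen = rank_by_energy(pool)[:n_lowest]
    rmsds = pool_rmsds(chosen, native)
    return float(100.0 * np.mean(rmsds < cutoff))


@dataclass
class BlindSelection:
    first: ModelRecord
    best: ModelRecord
    first_rmsd: float
    best_rmsd: float


def first_prediction(pool: list[ModelRecord]) -> ModelRecord:
    """The model with the lowest energy (ties by model_id)."""
    if not pool:
        raise ValueError("empty model pool")
    return rank_by_energy(pool)[0]


def blind_select(pool: list[ModelRecord], native, top_n: int = 5) -> BlindSelection:
    """Energy-driven selection, scored retrospectively against the native.

    ``first`` is the lowest-energy model; ``best`` is the smallest-RMSD
    model among the ``top_n`` lowest energies.
    """
    if native is None:
        raise ValueError("native structure required to score the best prediction")
    if len(pool) < top_n:
        raise ValueError(f"pool size {len(pool)} < top_n {top_n}")
    top = rank_by_energy(pool)[:top_n]
    rmsds = pool_rmsds(top, native)
    best_idx = int(np.argmin(rmsds))
    return BlindSelection(
        first=top[0],
        best=top[best_idx],
        first_rmsd=float(rmsds[0]),
        best_rmsd=float(rmsds[best_idx]),
    )


def summarize_quality(
    pool: list[ModelRecord],
    native,
    fractions: tuple[float, ...] = (0.001, 0.01),
) -> pd.DataFrame:
    """Mean RMSD of the best q-fraction of models, plus the single best.

    Mirrors the "1 permille / 1% lowest CA RMSD" pool-quality summaries:
    for each fraction q the mean of the ceil(q * |pool|) smallest RMSDs.
    """
    if not pool:
        raise ValueError("empty model pool")
    rmsds = np.sort(pool_rmsds(pool, native))
    rows = []
    for q in fractions:
        if not (0 < q <= 1):
            raise ValueError(f"fraction {q} outside (0, 1]")
        k = int(np.ceil(q * len(rmsds)))
        rows.append({"fraction": q, "mean_rmsd": float(rmsds[:k].mean()), "n": k})
    rows.append({"fraction": 0.0, "mean_rmsd": float(rmsds[0]), "n": 1})
    df = pd.DataFrame(rows)
    df.attrs["note"] = "fraction 0.0 row is the single best model"
    return df


def histogram_by_iteration(
    pool: list[ModelRecord],
    field: str = "energy",
    bins: int = 20,
    native=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-iteration histograms of energy or RMSD with shared bin edges."""
    if field == "energy":
        values = np.array([r.energy for r in pool])
    elif field == "rmsd":
        if native is None:
            raise ValueError("native structure required for RMSD histograms")
        values = pool_rmsds(pool, native)
    else:
        raise ValueError("field must be 'energy' or 'rmsd'")
    iterations = np.array([r.iteration for r in pool])
    edges = np.histogram_bin_edges(values, bins=bins)
    rows = {}
    for t in range(1, int(iterations.max()) + 1):
        counts, _ = np.histogram(values[iterations == t], bins=edges)
        rows[t] = counts
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "iteration"
    df.columns = [f"bin{j}" for j in range(len(edges) - 1)]
    return edges, df
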