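"""The estimation-of-distribution loop over fragment libraries.

The driver iterates T rounds (default 4).  Each round builds an equal share
of the total model budget (so 25% per round when T=4) by fragment-insertion
sampling under the current per-window probability mass functions, starting
from uniform probabilities in round 1.  After each round, the lowest-energy
fraction of the model pool (default 10%) becomes the sample set; for every
window, the observed frequency f_i of each fragment among the sample-set
models' provenance is mixed into the probabilities with a conservation rate
k:

    p_i(t + 1) = k * p_i(t) + (1 - k) * f_i          (k = 0.6 by default)

so the distribution drifts toward fragments that keep appearing in low
energy models while retaining mass on the rest of the library.  Models are
never re-sampled: every round's models stay in the final pool, tagged with
their iteration.
"""

from __future__ import annotations

import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .energy import ScoreFunction
from .fragment_io import FragmentLibrary, FragmentWindow
from .sampler import (
    ModelRecord,
    Pmf,
    SamplerConfig,
    build_model,
    uniform_pmfs,
)

__all__ = [
    "EdaConfig",
    "EdaState",
    "ModelRecord",
    "init_pmfs",
    "select_sample_set",
    "estimate_frequencies",
    "update_pmf",
    "run_eda",
    "model_rng",
]


@dataclass
class EdaConfig:
    budget: int = 400
    iterations: int = 4
    sample_fraction: float = 0.10
    conservation_rate: float = 0.6
    sample_base: str = "cumulative"  # or "iteration"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.budget < self.iterations:
            raise ValueError("budget must be >= iterations")
        if self.budget % self.iterations != 0:
            raise ValueError(
                f"budget {self.budget} not divisible by {self.iterations} "
                "iterations: equal per-iteration shares are required"
            )
        if not (0 < self.sample_fraction <= 1):
            raise ValueError("sample_fraction must be in (0, 1]")
        if not (0 <= self.conservation_rate <= 1):
            raise ValueError("conservation_rate must be in [0, 1]")
        if self.sample_base not in ("cumulative", "iteration"):
            raise ValueError("sample_base must be 'cumulative' or 'iteration'")


@dataclass
class EdaState:
    """Result of a run: final distributions, full pool, per-round history."""

    iteration: int
    pmfs9: list[Pmf]
    pmfs3: list[Pmf]
    pool: list[ModelRecord]
    # pmf_history9[t-1] holds the 9-mer Pmfs in effect while iteration t
    # was generating models (entry 0 is the uniform initialization).
    pmf_history9: list[list[Pmf]] = field(default_factory=list)
    eda_config: EdaConfig | None = None
    sampler_config: SamplerConfig | None = None
    master_seed: int | None = None


def init_pmfs(windows: list[FragmentWindow]) -> list[Pmf]:
    """Uniform distribution over every window's fragment list."""
    return uniform_pmfs(windows)


def select_sample_set(pool: list[ModelRecord], fraction: float) -> list[ModelRecord]:
    """The ceil(fraction * |pool|) lowest-energy models, ties by model_id."""
    if not pool:
        raise ValueError("empty model pool")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(pool))
    return sorted(pool, key=lambda r: (r.energy, r.model_id))[:k]


def _window_counts(sample: list[ModelRecord], window: FragmentWindow) -> np.ndarray:
    counts = np.zeros(window.n_fragments)
    for rec in sample:
        fi = rec.provenance9.get(window.start)
        if fi is not None and 0 <= fi < window.n_fragments:
            counts[fi] += 1
    return counts


def estimate_frequencies(sample: list[ModelRecord], window: FragmentWindow) -> np.ndarray:
    """Observed fragment usage frequencies at one window.

    Counts sample-set models whose 9-mer provenance covers the window;
    normalizes by the number of covering models.  Falls back to the uniform
    vector when no model covers the window.
    """
    if not sample:
        raise ValueError("empty sample set")
    counts = _window_counts(sample, window)
    covered = counts.sum()
    if covered == 0:
        return np.full(window.n_fragments, 1.0 / window.n_fragments)
    return counts / covered


def update_pmf(pmf: Pmf, freqs: np.ndarray, k: float) -> Pmf:
    """Conservation-rate mixture: p'_i = k * p_i + (1 - k) * f_i."""
    f = np.asarray(freqs, dtype=float)
    if len(f) != len(pmf.probs):
        raise ValueError(
            f"window {pmf.window_start}: frequency vector length {len(f)} != "
            f"pmf length {len(pmf.probs)}"
        )
    if not (0 <= k <= 1):
        raise ValueError("conservation rate k must be in [0, 1]")
    return Pmf(pmf.window_start, k * pmf.probs + (1.0 - k) * f)


def model_rng(master_seed: int, iteration: int, model_id: int) -> np.random.Generator:
    """Per-model random stream derived by a counter-based seed split.

    Every model is reproducible in isolation from (master_seed, iteration,
    model_id), independent of build order and worker count.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(iteration), int(model_id)])
    )


def _build_one(args) -> ModelRecord:
    (sequence, library, pmfs9, pmfs3, score, sampler_config, master_seed,
     iteration, model_id) = args
    rng = model_rng(master_seed, iteration, model_id)
    return build_model(
        sequence, library, pmfs9, pmfs3, score, sampler_config, rng,
        iteration=iteration, model_id=model_id,
    )


def run_eda(
    sequence: str,
    library: FragmentLibrary,
    score: ScoreFunction,
    eda_config: EdaConfig | None = None,
    sampler_config: SamplerConfig | None = None,
    master_seed: int = 0,
    workers: int = 1,
    refine_hook=None,
    progress=None,
) -> EdaState:
    """Run the full iterative loop; returns the final state with all models.

    Parameters
    ----------
    refine_hook:
        Optional callable ``ModelRecord -> ModelRecord`` applied to each
        model before it joins the pool (the seam where an all-atom
        refinement step would sit); identity when None.
    progress:
        Optional callable receiving a per-iteration summary dict.
    """
    eda_config = eda_config or EdaConfig()
    sampler_config = sampler_config or SamplerConfig()
    if library.target_length != len(sequence):
        raise ValueError("library does not cover the sequence")
    if not library.windows9:
        raise ValueError("library has no 9-mer windows")

    pmfs9 = init_pmfs(library.windows9)
    pmfs3 = init_pmfs(library.windows3) if library.windows3 else []
    per_iter = eda_config.budget // eda_config.iterations
    pool: list[ModelRecord] = []
    history: list[list[Pmf]] = []
    k = eda_config.conservation_rate

    executor = ProcessPoolExecutor(max_workers=workers) if workers > 1 else None
    try:
        for t in range(1, eda_config.iterations + 1):
            history.append([Pmf(p.window_start, p.probs.copy()) for p in pmfs9])
            ids = range((t - 1) * per_iter, t * per_iter)
            tasks = [
                (sequence, library, pmfs9, pmfs3, score, sampler_config,
                 master_seed, t, mid)
                for mid in ids
            ]
            if executor is not None:
                batch = list(executor.map(_build_one, tasks, chunksize=4))
            else:
                batch = [_build_one(task) for task in tasks]
            if refine_hook is not None:
                batch = [refine_hook(rec) for rec in batch]
            pool.extend(batch)

            base = pool if eda_config.sample_base == "cumulative" else batch
            sample = select_sample_set(base, eda_config.sample_fraction)
            for wi, window in enumerate(library.windows9):
                counts = _window_counts(sample, window)
                if counts.sum() == 0:
                    # No sample-set model covers this window: keep the
                    # learned distribution rather than washing it out.
                    continue
                pmfs9[wi] = update_pmf(pmfs9[wi], counts / counts.sum(), k)
            if sampler_config.learn_3mers and library.windows3:
                for wi, window in enumerate(library.windows3):
                    counts = np.zeros(window.n_fragments)
                    for rec in sample:
                        fi = rec.conformation.provenance3.get(window.start)
                        if fi is not None and 0 <= fi < window.n_fragments:
                            counts[fi] += 1
                    if counts.sum() == 0:
                        continue
                    pmfs3[wi] = update_pmf(pmfs3[wi], counts / counts.sum(), k)
            if progress is not None:
                energies = np.array([r.energy for r in batch])
                progress(
                    {
                        "iteration": t,
                        "pool_size": len(pool),
                        "min_energy": float(min(r.energy for r in pool)),
                        "mean_energy": float(energies.mean()),
                        "mean_pmf_entropy": float(
                            np.mean(
                                [
                                    -np.sum(p.probs[p.probs > 0] * np.log(p.probs[p.probs > 0]))
                                    for p in pmfs9
                                ]
                            )
                        ),
                    }
                )
    finally:
        if executor is not None:
            executor.shutdown()

    return EdaState(
        iteration=eda_config.iterations,
        pmfs9=pmfs9,
        pmfs3=pmfs3,
        pool=pool,
        pmf_history9=history,
        eda_config=eda_config,
        sampler_config=sampler_config,
        master_seed=master_seed,
    )
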