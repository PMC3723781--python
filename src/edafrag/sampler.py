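"""Stochastic fragment-insertion sampling of one coarse-grained model.

A model is grown from the extended chain by repeatedly choosing a sequence
window, drawing a candidate fragment from that window's probability mass
function with a roulette wheel, and splicing the fragment's torsions into
the chain.  The move stream alternates simulated annealing (Metropolis
acceptance under a geometrically cooled temperature) with iterated hill
climbing (greedy descent punctuated by unconditional "kick" insertions,
keeping the best conformation ever seen).  9-mer windows are assembled
first, then 3-mers refine the result.

All randomness flows through a single ``numpy.random.Generator``, so a model
build is bit-reproducible given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conformation import (
    Conformation,
    apply_provenance,
    build_coords,
    extended_conformation,
)
from .energy import ScoreFunction
from .fragment_io import FragmentLibrary, FragmentWindow

__all__ = [
    "Pmf",
    "AnnealingSchedule",
    "SamplerConfig",
    "SamplerStats",
    "ModelRecord",
    "uniform_pmf",
    "uniform_pmfs",
    "roulette_select",
    "metropolis_accept",
    "sa_stage",
    "ihc_stage",
    "build_model",
]


@dataclass
class Pmf:
    """Probability vector over one window's fragment list."""

    window_start: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1:
            raise ValueError("probs must be a vector")
        if np.any(p < 0):
            raise ValueError(f"window {self.window_start}: negative probability")
        total = p.sum()
        if not math.isfinite(total) or abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"window {self.window_start}: probabilities sum to {total}, not 1"
            )
        self.probs = p


def uniform_pmf(window: FragmentWindow) -> Pmf:
    m = window.n_fragments
    return Pmf(window.start, np.full(m, 1.0 / m))


def uniform_pmfs(windows: list[FragmentWindow]) -> list[Pmf]:
    return [uniform_pmf(w) for w in windows]


def roulette_select(pmf: Pmf, rng: np.random.Generator) -> int:
    """Fitness-proportionate (roulette wheel) draw of a fragment index."""
    probs = pmf.probs.tolist()
    total = math.fsum(probs)
    if total <= 0:
        raise ValueError(f"window {pmf.window_start}: zero-sum probabilities")
    r = rng.random() * total
    acc = 0.0
    for i, p in enumerate(probs):
        acc += p
        if r < acc:
            return i
    return len(probs) - 1


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept if the move improves, else with probability exp(-dE/T)."""
    if delta_e <= 0:
        return True
    if temperature <= 0:
        return False
    return rng.random() < math.exp(-delta_e / temperature)


@dataclass
class AnnealingSchedule:
    """Geometric cooling from t_start to t_end over n_steps move attempts."""

    t_start: float = 2.0
    t_end: float = 0.01
    n_steps: int = 100
    cooling: float | None = None  # per-step factor; derived when None

    def __post_init__(self) -> None:
        if not (self.t_start >= self.t_end > 0):
            raise ValueError("need t_start >= t_end > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.cooling is None:
            if self.n_steps > 1:
                self.cooling = (self.t_end / self.t_start) ** (1.0 / (self.n_steps - 1))
            else:
                self.cooling = 1.0


@dataclass
class SamplerStats:
    """Move bookkeeping, filled in by sa_stage when passed."""

    proposed: int = 0
    accepted: int = 0


@dataclass
class SamplerConfig:
    """Tunables of one model build; all counts scale with window count."""

    sa_steps_per_window: int = 20
    t_start: float = 2.0
    t_end: float = 0.01
    # The 3-mer stage refines the fold established by the 9-mers; it anneals
    # from a lower temperature so it cannot re-melt the model.
    t_start_3mer: float = 0.3
    ihc_restarts: int = 3
    ihc_steps_per_window: int = 8
    kick_size: int = 2
    # How insertions update the provenance record: "keep" counts the last
    # fragment used at each window during construction (feeds the frequency
    # estimate even when a later overlapping insertion retouched residues);
    # "invalidate" clears partially overwritten windows.
    provenance_policy: str = "keep"
    learn_3mers: bool = False  # consumed by the iteration driver


@dataclass
class ModelRecord:
    """A finished model with its recorded energy and provenance snapshot."""

    conformation: Conformation
    energy: float
    iteration: int
    model_id: int
    provenance9: dict[int, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Internal mutable state used by the stages (raw arrays, no dataclass
# overhead in the move loop).
# ---------------------------------------------------------------------------


class _State:
    __slots__ = ("torsions", "coords", "energy", "prov", "other_prov", "geometry", "policy")

    def __init__(
        self,
        conf: Conformation,
        score: ScoreFunction,
        frag_length: int,
        policy: str = "keep",
    ):
        self.policy = policy
        self.torsions = conf.torsions.copy()
        self.coords = conf.coords.copy()
        self.energy = score.energy_from_coords(self.coords)
        self.geometry = conf.geometry
        if frag_length == 3:
            self.prov = dict(conf.provenance3)
            self.other_prov = dict(conf.provenance9)
        else:
            self.prov = dict(conf.provenance9)
            self.other_prov = dict(conf.provenance3)

    def snapshot(self):
        return (self.torsions.copy(), self.coords.copy(), self.energy, dict(self.prov))

    def restore(self, snap) -> None:
        self.torsions, self.coords, self.energy, self.prov = (
            snap[0].copy(),
            snap[1].copy(),
            snap[2],
            dict(snap[3]),
        )

    def to_conformation(self, conf: Conformation, frag_length: int) -> Conformation:
        out = conf.copy()
        out.torsions = self.torsions
        out.coords = self.coords
        if frag_length == 3:
            out.provenance3 = self.prov
            out.provenance9 = self.other_prov
        else:
            out.provenance9 = self.prov
            out.provenance3 = self.other_prov
        return out


def _propose(
    state: _State, window: FragmentWindow, frag_index: int
) -> tuple[np.ndarray, np.ndarray]:
    frag = window.fragments[frag_index]
    length = frag.length
    s0 = window.start - 1
    new_t = state.torsions.copy()
    new_t[s0 : s0 + length] = frag.torsions
    new_c = state.coords.copy()
    # Residues before the window are untouched; phi of the window's first
    # residue only matters from that residue's C atom onward.
    build_coords(new_t, state.geometry, coords=new_c, start=max(s0, 1))
    return new_t, new_c


def _apply(
    state: _State,
    window: FragmentWindow,
    frag_index: int,
    new_t: np.ndarray,
    new_c: np.ndarray,
    energy: float,
) -> None:
    state.torsions = new_t
    state.coords = new_c
    state.energy = energy
    apply_provenance(
        state.prov, window.start, window.fragments[0].length, frag_index,
        policy=state.policy,
    )


def _check_stage_inputs(windows: list[FragmentWindow], pmfs: list[Pmf]) -> int:
    if not windows:
        raise ValueError("no windows to sample")
    lengths = {w.length for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"stage windows must share one length, got {sorted(lengths)}")
    if len(pmfs) != len(windows):
        raise ValueError("one Pmf per window required")
    for w, p in zip(windows, pmfs):
        if p.window_start != w.start or len(p.probs) != w.n_fragments:
            raise ValueError(f"Pmf misaligned with window {w.start}")
    return lengths.pop()


def sa_stage(
    conf: Conformation,
    windows: list[FragmentWindow],
    pmfs: list[Pmf],
    score: ScoreFunction,
    schedule: AnnealingSchedule,
    rng: np.random.Generator,
    stats: SamplerStats | None = None,
    provenance_policy: str = "keep",
) -> Conformation:
    """Simulated annealing over fragment insertions.

    Each step picks a window uniformly, a fragment by roulette wheel, and
    accepts the insertion by the Metropolis criterion at the current
    temperature, which cools geometrically from ``t_start`` to ``t_end``.
    """
    frag_length = _check_stage_inputs(windows, pmfs)
    state = _State(conf, score, frag_length, policy=provenance_policy)
    n_windows = len(windows)
    temperature = schedule.t_start
    for _ in range(schedule.n_steps):
        wi = int(rng.integers(n_windows))
        fi = roulette_select(pmfs[wi], rng)
        new_t, new_c = _propose(state, windows[wi], fi)
        e_new = score.energy_from_coords(new_c)
        if stats is not None:
            stats.proposed += 1
        if metropolis_accept(e_new - state.energy, temperature, rng):
            _apply(state, windows[wi], fi, new_t, new_c, e_new)
            if stats is not None:
                stats.accepted += 1
        temperature = max(temperature * schedule.cooling, schedule.t_end)
    return state.to_conformation(conf, frag_length)


def ihc_stage(
    conf: Conformation,
    windows: list[FragmentWindow],
    pmfs: list[Pmf],
    score: ScoreFunction,
    n_restarts: int,
    n_steps: int,
    kick_size: int,
    rng: np.random.Generator,
    provenance_policy: str = "keep",
) -> Conformation:
    """Iterated hill climbing: greedy descent with perturbation kicks.

    Each round runs ``n_steps`` greedy proposals (accept only non-worsening
    moves), updates the best-ever conformation, then perturbs with
    ``kick_size`` unconditional insertions before the next round.  The
    best-ever conformation is returned, so the result is never worse than
    the input.
    """
    frag_length = _check_stage_inputs(windows, pmfs)
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    state = _State(conf, score, frag_length, policy=provenance_policy)
    best = state.snapshot()
    n_windows = len(windows)
    for restart in range(n_restarts):
        for _ in range(n_steps):
            wi = int(rng.integers(n_windows))
            fi = roulette_select(pmfs[wi], rng)
            new_t, new_c = _propose(state, windows[wi], fi)
            e_new = score.energy_from_coords(new_c)
            if e_new <= state.energy:
                _apply(state, windows[wi], fi, new_t, new_c, e_new)
        if state.energy < best[2]:
            best = state.snapshot()
        if restart < n_restarts - 1:
            for _ in range(kick_size):
                wi = int(rng.integers(n_windows))
                fi = roulette_select(pmfs[wi], rng)
                new_t, new_c = _propose(state, windows[wi], fi)
                _apply(
                    state,
                    windows[wi],
                    fi,
                    new_t,
                    new_c,
                    score.energy_from_coords(new_c),
                )
    state.restore(best)
    return state.to_conformation(conf, frag_length)


def build_model(
    sequence: str,
    library: FragmentLibrary,
    pmfs9: list[Pmf],
    pmfs3: list[Pmf],
    score: ScoreFunction,
    config: SamplerConfig,
    rng: np.random.Generator,
    iteration: int = 1,
    model_id: int = 0,
) -> ModelRecord:
    """Assemble one coarse-grained model from the extended conformation.

    The 9-mer stage (SA then IHC) establishes the global fold; the 3-mer
    stage refines it.  The recorded energy is ``score.record_energy`` on the
    final conformation -- for the oracle scorer this is where the optional
    per-model noise is drawn.
    """
    if library.target_length != len(sequence):
        raise ValueError(
            f"library target length {library.target_length} != sequence "
            f"length {len(sequence)}"
        )
    conf = extended_conformation(sequence)
    for windows, pmfs in ((library.windows9, pmfs9), (library.windows3, pmfs3)):
        if not windows:
            continue
        n_windows = len(windows)
        t_start = config.t_start if windows[0].length == 9 else config.t_start_3mer
        schedule = AnnealingSchedule(
            t_start=max(t_start, config.t_end),
            t_end=config.t_end,
            n_steps=config.sa_steps_per_window * n_windows,
        )
        conf = sa_stage(
            conf, windows, pmfs, score, schedule, rng,
            provenance_policy=config.provenance_policy,
        )
        conf = ihc_stage(
            conf,
            windows,
            pmfs,
            score,
            config.ihc_restarts,
            config.ihc_steps_per_window * n_windows,
            config.kick_size,
            rng,
            provenance_policy=config.provenance_policy,
        )
    energy = float(score.record_energy(conf, rng))
    return ModelRecord(
        conformation=conf,
        energy=energy,
        iteration=iteration,
        model_id=model_id,
        provenance9=dict(conf.provenance9),
    )
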