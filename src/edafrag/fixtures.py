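"""Synthetic targets with planted funnels, for offline testing of the loop.

The generator invents a clash-free "native" backbone from secondary
structure regimes (helix / strand / coil segments), then manufactures a
fragment library around it: each window holds a configurable number of
near-native fragments (native torsions plus a small jitter) hidden among
noisy decoys (native torsions plus a large jitter), shuffled so the
near-native fragment sits at a random index.  Paired with the oracle score
this yields a controlled funnel landscape in which near-native enrichment
is measurable without any external data.

Everything is a pure function of the spec (seed included).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .conformation import (
    Conformation,
    build_coords,
    canonicalize_torsions,
    write_pdb,
)
from .fragment_io import (
    Fragment,
    FragmentLibrary,
    FragmentWindow,
    write_fragment_file,
    write_sequence,
)

__all__ = ["FixtureSpec", "FixtureSet", "make_native", "make_library", "make_fixture", "write_fixture"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CLASH_CUTOFF = 4.0  # min CA-CA distance (A) for pairs >= 3 residues apart

# (phi, psi) regime centers
_HELIX = (-60.0, -45.0)
_STRAND = (-120.0, 130.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic target.

    Defaults mirror the desk-scale study conditions: a 36-residue target
    with 25 candidate fragments per window, one planted near-native fragment
    per window (2 degree jitter) among decoys jittered by 60 degrees.
    """

    length: int = 36
    frags_per_window: int = 25
    native_frac: int = 1
    torsion_noise_sd: float = 60.0
    near_native_jitter_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 9:
            raise ValueError("length must be >= 9")
        if self.frags_per_window < 2:
            raise ValueError("frags_per_window must be >= 2")
        if not (1 <= self.native_frac < self.frags_per_window):
            raise ValueError("native_frac must be in [1, frags_per_window)")


@dataclass
class FixtureSet:
    spec: FixtureSpec
    sequence: str
    native_torsions: np.ndarray
    native_coords: np.ndarray
    library: FragmentLibrary


def _min_nonlocal_ca_distance(coords: np.ndarray) -> float:
    ca = coords[:, 1, :]
    n = len(ca)
    diff = ca[:, None, :] - ca[None, :, :]
    d = np.sqrt((diff * diff).sum(axis=2))
    iu, ju = np.triu_indices(n, k=3)
    return float(d[iu, ju].min()) if len(iu) else float("inf")


def _sample_torsions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-residue torsions from helix/strand/coil segments with jitter."""
    torsions = np.empty((n, 3))
    pos = 0
    while pos < n:
        seg_len = int(rng.integers(6, 13))
        kind = rng.choice(("helix", "strand", "coil"), p=(0.5, 0.3, 0.2))
        for _ in range(seg_len):
            if pos >= n:
                break
            if kind == "helix":
                phi, psi = _HELIX
                phi += rng.normal(0, 5.0)
                psi += rng.normal(0, 5.0)
            elif kind == "strand":
                phi, psi = _STRAND
                phi += rng.normal(0, 8.0)
                psi += rng.normal(0, 8.0)
            else:
                phi = rng.uniform(-160.0, -50.0)
                psi = rng.uniform(-70.0, 170.0)
            torsions[pos] = (phi, psi, 180.0)
            pos += 1
    return canonicalize_torsions(torsions)


def make_native(
    spec: FixtureSpec, max_attempts: int = 200
) -> tuple[str, np.ndarray, np.ndarray]:
    """Generate (sequence, native torsions, native coords); clash-rejected.

    Torsion paths are resampled until no CA pair three or more residues
    apart comes closer than 4 A.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    sequence = "".join(rng.choice(list(_AA), size=spec.length))
    best_min = -np.inf
    for _ in range(max_attempts):
        torsions = _sample_torsions(spec.length, rng)
        coords = build_coords(torsions)
        dmin = _min_nonlocal_ca_distance(coords)
        best_min = max(best_min, dmin)
        if dmin >= _CLASH_CUTOFF:
            return sequence, torsions, coords
    raise RuntimeError(
        f"could not generate a clash-free native in {max_attempts} attempts "
        f"(best min CA-CA distance {best_min:.2f} A < {_CLASH_CUTOFF} A); "
        f"spec={spec}"
    )


def _jitter(
    base: np.ndarray, phi_psi_sd: float, omega_sd: float, rng: np.random.Generator
) -> np.ndarray:
    t = base.copy()
    t[:, 0] += rng.normal(0, phi_psi_sd, len(t))
    t[:, 1] += rng.normal(0, phi_psi_sd, len(t))
    t[:, 2] += rng.normal(0, omega_sd, len(t))
    return canonicalize_torsions(t)


def make_library(spec: FixtureSpec, native_torsions: np.ndarray) -> FragmentLibrary:
    """Dense 9-mer and 3-mer windows with planted near-native fragments.

    Per window: ``native_frac`` fragments are the native torsions with a
    small jitter (near-native); the rest are decoys jittered by
    ``torsion_noise_sd`` on phi/psi.  Omega stays near trans (180) for all
    fragments.  Order is shuffled so near-native indices are random.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = spec.length

    def build_windows(length: int) -> list[FragmentWindow]:
        windows = []
        for start in range(1, n - length + 2):
            base = native_torsions[start - 1 : start - 1 + length]
            frags = []
            for _ in range(spec.native_frac):
                frags.append(
                    _jitter(base, spec.near_native_jitter_sd,
                            min(spec.near_native_jitter_sd, 1.0), rng)
                )
            for _ in range(spec.frags_per_window - spec.native_frac):
                frags.append(_jitter(base, spec.torsion_noise_sd, 2.0, rng))
            order = rng.permutation(len(frags))
            fragments = [
                Fragment(frags[j], source_tag=f"synt A {start}")
                for j in order
            ]
            windows.append(FragmentWindow(start=start, fragments=fragments))
        return windows

    return FragmentLibrary(
        target_length=n, windows9=build_windows(9), windows3=build_windows(3)
    )


def make_fixture(spec: FixtureSpec) -> FixtureSet:
    """Native plus library; pure function of the spec."""
    sequence, torsions, coords = make_native(spec)
    library = make_library(spec, torsions)
    return FixtureSet(
        spec=spec,
        sequence=sequence,
        native_torsions=torsions,
        native_coords=coords,
        library=library,
    )


def write_fixture(fixture: FixtureSet, outdir) -> dict[str, Path]:
    """Write FASTA, fragment files, native PDB and spec JSON to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequence": outdir / "target.fasta",
        "fragments9": outdir / "frags9.txt",
        "fragments3": outdir / "frags3.txt",
        "native": outdir / "native.pdb",
        "spec": outdir / "fixture_spec.json",
    }
    write_sequence(fixture.sequence, paths["sequence"])
    write_fragment_file(fixture.library.windows9, paths["fragments9"])
    write_fragment_file(fixture.library.windows3, paths["fragments3"])
    native_conf = Conformation(
        sequence=fixture.sequence,
        torsions=fixture.native_torsions,
        coords=fixture.native_coords,
    )
    write_pdb(native_conf, paths["native"])
    paths["spec"].write_text(json.dumps(asdict(fixture.spec), indent=2) + "\n")
    return paths
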