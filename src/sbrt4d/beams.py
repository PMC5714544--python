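"""Non-coplanar candidate cone beams and per-phase aperture shifting.

Candidate source points sit on the anterior hemisphere (z > 0: no beam
enters through the couch) of a sphere of radius SAD around the target,
placed by a Fibonacci lattice for determinism.  Real-time tracking is
emulated by rigidly translating the beam with the target: the aperture
shift of phase p equals the GTV centroid displacement of phase p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Beam", "BeamSet", "generate_candidates", "shift_aperture"]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class Beam:
    source: tuple[float, float, float]
    direction: tuple[float, float, float]  # unit vector
    aperture_radius_mm: float  # circular field radius defined at SAD
    sad_mm: float = 800.0
    collimator_id: int = 0

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("beam direction must be a unit vector")
        if self.aperture_radius_mm <= 0:
            raise ValueError("aperture radius must be > 0")
        object.__setattr__(self, "source", tuple(float(v) for v in self.source))
        object.__setattr__(self, "direction", tuple(float(v) for v in d))

    @property
    def source_arr(self) -> np.ndarray:
        return np.asarray(self.source)

    @property
    def direction_arr(self) -> np.ndarray:
        return np.asarray(self.direction)


@dataclass
class BeamSet:
    beams: list[Beam]
    weights: np.ndarray = field(default=None)  # MU per beam

    def __post_init__(self):
        if self.weights is None:
            self.weights = np.zeros(len(self.beams))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.beams):
            raise ValueError("one weight per beam required")
        if (self.weights < 0).any():
            raise ValueError("beam weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.beams)

    def with_weights(self, weights) -> "BeamSet":
        return BeamSet(list(self.beams), np.asarray(weights, dtype=float))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beams": [
                {
                    "source": b.source,
                    "direction": b.direction,
                    "aperture_radius_mm": b.aperture_radius_mm,
                    "sad_mm": b.sad_mm,
                    "collimator_id": b.collimator_id,
                }
                for b in self.beams
            ],
            "weights": self.weights.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BeamSet":
        payload = json.loads(Path(path).read_text())
        beams = [Beam(**{**b, "source": tuple(b["source"]), "direction": tuple(b["direction"])}) for b in payload["beams"]]
        return cls(beams, np.asarray(payload["weights"]))


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors with z > 0."""
    i = np.arange(n)
    z = (i + 0.5) / n  # strictly positive
    r = np.sqrt(1.0 - z**2)
    phi = i * GOLDEN_ANGLE
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def generate_candidates(
    n_nodes: int,
    collimator_radii: list[float] | tuple[float, ...],
    target_point,
    sad_mm: float = 800.0,
) -> BeamSet:
    """One candidate beam per (node, collimator), all aimed at the target.

    With n nodes and two or three collimators this yields exactly 2n or 3n
    candidate beams; weights are initialized to zero.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    radii = [float(r) for r in collimator_radii]
    if not radii or any(r <= 0 for r in radii):
        raise ValueError("collimator radii must be positive and nonempty")
    target = np.asarray(target_point, dtype=float)
    nodes = _fibonacci_hemisphere(n_nodes)
    beams = []
    for node in nodes:
        source = target + sad_mm * node
        direction = (target - source)
        direction = direction / np.linalg.norm(direction)
        for cid, radius in enumerate(radii):
            beams.append(
                Beam(
                    source=tuple(source),
                    direction=tuple(direction),
                    aperture_radius_mm=radius,
                    sad_mm=sad_mm,
                    collimator_id=cid,
                )
            )
    return BeamSet(beams)


def shift_aperture(beam: Beam, displacement) -> Beam:
    """Translate the beam rigidly with the target (direction unchanged)."""
    disp = np.asarray(displacement, dtype=float)
    if not np.all(np.isfinite(disp)):
        raise ValueError("displacement must be finite")
    return replace(beam, source=tuple(beam.source_arr + disp))


def shift_beamset(beamset: BeamSet, displacement) -> BeamSet:
    return BeamSet([shift_aperture(b, displacement) for b in beamset.beams], beamset.weights.copy())
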