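"""Shared fixtures: small known-answer inputs built programmatically."""

import numpy as np
import pytest

import hermesmap as hm


@pytest.fixture
def toy_pmap():
    """The worked parsimony toy: P1={a,b,c}, P2={c,d}, P3={c}."""
    return {
        "a": frozenset({"P1"}),
        "b": frozenset({"P1"}),
        "c": frozenset({"P1", "P2", "P3"}),
        "d": frozenset({"P2"}),
    }


@pytest.fixture
def small_proteome():
    return hm.generate_proteome(12, 3, seed=42)


@pytest.fixture
def square_scene():
    """A hand-built scene: 1000 nm square plasma membrane, one horizontal
    cisterna through the middle, one small flagellar circle, no jitter."""
    pm = hm.Structure(
        "plasma_membrane",
        "cross",
        ((0.0, 0.0), (1000.0, 0.0), (1000.0, 1000.0), (0.0, 1000.0)),
        closed=True,
    )
    cis = hm.Structure("cisterna", "cross", ((200.0, 500.0), (800.0, 500.0)))
    theta = np.linspace(0, 2 * np.pi, 17)[:-1]
    fla = hm.Structure(
        "flagellum",
        "oblique",
        tuple((500.0 + 80 * np.cos(t), 820.0 + 80 * np.sin(t)) for t in theta),
        closed=True,
    )

    def scene(particles):
        return hm.GoldScene(
            scene_id="s0",
            animal="rat1",
            dilution="1:5",
            is_control=False,
            structures=[pm, cis, fla],
            particles=[hm.Particle(*p) for p in particles],
        )

    return scene


def brute_force_polyline_distance(point, structure):
    """Independent per-segment point-to-polyline distance oracle."""
    pts = list(structure.points)
    if structure.closed:
        pts = pts + [pts[0]]
    px, py = point
    best = np.inf
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        dx, dy = x1 - x0, y1 - y0
        L2 = dx * dx + dy * dy
        t = 0.0 if L2 == 0 else max(0.0, min(1.0, ((px - x0) * dx + (py - y0) * dy) / L2))
        best = min(best, np.hypot(px - (x0 + t * dx), py - (y0 + t * dy)))
    return best
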