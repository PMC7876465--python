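"""Two-variable excitable-medium simulator (Barkley kinetics).

Used to produce wavefront phenomenology — expanding target waves, and broken
waves / reentry after a cross-field premature stimulus — against which the
wave-break detector can be exercised.  The model is

    du/dt = (1/eps) * u * (1 - u) * (u - (v + b) / a) + D * lap(u)
    dv/dt = u - v

integrated by explicit Euler with a 5-point Laplacian and no-flux boundaries.
``u`` is the fast excitation variable (normalized to [0, 1]); ``v`` the slow
recovery variable.  Model time is in dimensionless units; callers attach a
frame interval when converting recorded frames into a movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExcitableParams:
    """Barkley-model parameters (defaults support rigidly rotating spirals)."""

    a: float = 0.75
    b: float = 0.06
    eps: float = 0.02
    diffusion: float = 1.0
    dx: float = 0.5
    dt: float = 0.01


@dataclass
class Stimulus:
    """One stimulus event: set u = 1 inside a region at a given model time.

    Regions: ``point`` (disc of ``radius`` grid cells around ``center``),
    ``left_edge`` (3-cell strip, launches a plane wave), ``lower_half`` /
    ``upper_half`` (cross-field S2 geometry).
    """

    time: float
    region: str
    center: tuple[int, int] | None = None
    radius: float = 3.0


def _region_mask(stim: Stimulus, n: int) -> np.ndarray:
    mask = np.zeros((n, n), dtype=bool)
    if stim.region == "point":
        cr, cc = stim.center if stim.center is not None else (n // 2, n // 2)
        r = np.arange(n)[:, None] - cr
        c = np.arange(n)[None, :] - cc
        mask = np.hypot(r, c) <= stim.radius
    elif stim.region == "left_edge":
        mask[:, :3] = True
    elif stim.region == "lower_half":
        mask[n // 2:, :] = True
    elif stim.region == "upper_half":
        mask[: n // 2, :] = True
    else:
        raise ValueError(f"unknown stimulus region {stim.region!r}")
    return mask


def simulate_excitable_medium(
    grid: int = 64,
    params: ExcitableParams | None = None,
    stimuli: tuple[Stimulus, ...] | list[Stimulus] = (),
    t_max: float = 30.0,
    record_every: int = 25,
) -> np.ndarray:
    """Integrate the medium and return recorded ``u`` frames (frames, grid, grid).

    Raises if the explicit time step is unstable for the requested diffusion
    (dt must stay below dx^2 / (4 D)).
    """
    p = params or ExcitableParams()
    dt_max = p.dx ** 2 / (4.0 * p.diffusion)
    if p.dt >= dt_max:
        raise ValueError(
            f"unstable time step: dt={p.dt} must be < dx^2/(4D) = {dt_max:.4g}"
        )
    n_steps = int(round(t_max / p.dt))
    u = np.zeros((grid, grid))
    v = np.zeros((grid, grid))
    stim_steps = {int(round(s.time / p.dt)): s for s in stimuli}
    frames = []
    coef = p.diffusion / p.dx ** 2
    for step in range(n_steps):
        if step in stim_steps:
            u[_region_mask(stim_steps[step], grid)] = 1.0
        if step % record_every == 0:
            frames.append(u.copy())
        padded = np.pad(u, 1, mode="edge")
        lap = (
            padded[:-2, 1:-1]
            + padded[2:, 1:-1]
            + padded[1:-1, :-2]
            + padded[1:-1, 2:]
            - 4.0 * u
        )
        reaction = u * (1.0 - u) * (u - (v + p.b) / p.a) / p.eps
        u = u + p.dt * (reaction + coef * lap)
        v = v + p.dt * (u - v)
        np.clip(u, 0.0, 1.0, out=u)
    return np.asarray(frames)


def cross_field_protocol(s2_time: float = 9.0) -> tuple[Stimulus, Stimulus]:
    """Standard S1 (plane wave from the left) + premature cross-field S2
    (lower half-field) protocol; an S2 inside the vulnerable window leaves a
    broken wavefront with a free end."""
    return (
        Stimulus(time=0.0, region="left_edge"),
        Stimulus(time=s2_time, region="lower_half"),
    )
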