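"""Ground-truth phantom generators.

Every stage of the pipeline can be exercised without real microscopy data:

* single-spheroid intensity phantoms — a disk with a prescribed radial
  intensity law (core-high, edge-high, flat, or custom) plus additive
  Gaussian noise, emulating read-noise-dominated widefield images of
  radially organised markers;
* multi-spheroid QC fields with known accept/reject labels (interior,
  border-clipped, and touching disks);
* TCSPC decay stacks drawn from a known biexponential model with Poisson
  photon statistics;
* statistical cohorts of per-region marker values with known means/SDs.

All generators are pure functions of (spec, seed): the same inputs yield
bit-identical outputs, and every downstream test can read the truth from
the returned manifest instead of re-deriving it from pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import DecayStack, ImageGrid

__all__ = [
    "PhantomSpec",
    "DecayPhantomSpec",
    "REFERENCE_MARKER_EFFECTS",
    "make_spheroid_image",
    "make_qc_field",
    "random_qc_layout",
    "decay_histogram",
    "make_decay_stack",
    "make_cohort",
]


#: Reference per-region effect sizes (mean, SD of min-max normalised
#: intensity) for the M1 (CD80) and M2 (CD206) macrophage markers, by
#: size class. These are realistic published-scale gradients: CD80 rises
#: toward the proliferative edge while CD206 concentrates in the core
#: (small spheroids) or quiescent zone (large spheroids).
REFERENCE_MARKER_EFFECTS = {
    "CD80": {
        ("small", "core"): (0.189, 0.212),
        ("small", "quiescent"): (0.364, 0.214),
        ("small", "edge"): (0.767, 0.089),
        ("large", "core"): (0.212, 0.123),
        ("large", "quiescent"): (0.494, 0.151),
        ("large", "edge"): (0.801, 0.184),
    },
    "CD206": {
        ("small", "core"): (0.826, 0.156),
        ("small", "quiescent"): (0.874, 0.085),
        ("small", "edge"): (0.521, 0.123),
        ("large", "core"): (0.420, 0.266),
        ("large", "quiescent"): (0.786, 0.139),
        ("large", "edge"): (0.620, 0.208),
    },
}


@dataclass
class PhantomSpec:
    """Specification of one synthetic spheroid image.

    ``profile_shape`` sets the radial intensity law I(r) for normalised
    radius r in [0, 1]: ``core_high`` = background + peak*(1-r),
    ``edge_high``/``linear_ramp`` = background + peak*r, ``flat`` =
    background + peak, or a custom callable of r returning a [0, 1]
    multiplier of ``peak_intensity``.
    """

    diameter_um: float = 240.0
    pixel_size_um: float = 2.0
    profile_shape: object = "core_high"
    peak_intensity: float = 200.0
    background: float = 5.0
    noise_sd: float = 0.0
    field_px: int = 200
    seed: int = 0


@dataclass
class DecayPhantomSpec:
    """Specification of a synthetic TCSPC decay stack.

    Defaults emulate a typical NADH acquisition: 256 bins over a 12.5 ns
    window (80 MHz repetition rate), free/bound lifetimes 0.4 / 2.5 ns,
    ~80% free contribution. ``core_params`` optionally assigns distinct
    (A1, A2, tau1_ns, tau2_ns) truth to a central disk covering
    ``core_radius_fraction`` of the field half-width.
    """

    A1: float = 0.8
    A2: float = 0.2
    tau1_ns: float = 0.4
    tau2_ns: float = 2.5
    photons_per_pixel: int = 5000
    nbins: int = 256
    window_ns: float = 12.5
    shape: tuple[int, int] = (16, 16)
    core_params: dict | None = None
    core_radius_fraction: float = 0.5
    pixel_size_um: float = 2.0
    seed: int = 0


def _radial_law(profile_shape, peak: float, background: float):
    if callable(profile_shape):
        return lambda r: background + peak * np.asarray(profile_shape(r), float)
    laws = {
        "core_high": lambda r: background + peak * (1.0 - r),
        "edge_high": lambda r: background + peak * r,
        "linear_ramp": lambda r: background + peak * r,
        "flat": lambda r: background + peak * np.ones_like(np.asarray(r, float)),
    }
    if profile_shape not in laws:
        raise ValueError(f"unknown profile shape {profile_shape!r}")
    return laws[profile_shape]


def make_spheroid_image(spec: PhantomSpec):
    """Render one spheroid phantom and its ground truth.

    Returns ``(ImageGrid, truth)`` where ``truth`` carries the binary
    mask, sub-pixel centroid, radius in pixels, and the radial intensity
    law used, so tests never have to re-derive geometry from pixels.
    """
    radius_px = spec.diameter_um / (2.0 * spec.pixel_size_um)
    if 2 * radius_px > 0.9 * spec.field_px:
        raise ValueError(
            f"diameter {spec.diameter_um} um does not fit the "
            f"{spec.field_px}px field with a QC margin"
        )
    n = spec.field_px
    # centre on an exact pixel centre so the truth centroid is representable
    center = (float(n // 2), float(n // 2))
    rr, cc = np.mgrid[0:n, 0:n]
    dist = np.hypot(rr - center[0], cc - center[1])
    r_norm = dist / radius_px
    mask = dist <= radius_px
    law = _radial_law(spec.profile_shape, spec.peak_intensity, spec.background)
    values = np.full((n, n), float(spec.background))
    values[mask] = law(r_norm[mask])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, values.shape)
    values = np.clip(values, 0.0, None)
    image = ImageGrid(values, spec.pixel_size_um, "phantom", 0)
    truth = {
        "mask": mask,
        "centroid": center,
        "radius_px": radius_px,
        "diameter_um": spec.diameter_um,
        "radial_law": law,
        "background": spec.background,
    }
    return image, truth


def make_qc_field(layout, seed: int = 0, shape: tuple[int, int] = (200, 200),
                  pixel_size_um: float = 2.0, intensity: float = 150.0,
                  background: float = 5.0, noise_sd: float = 2.0,
                  pair_gap_px: float = 2.0):
    """Render a multi-spheroid field with known accept/reject labels.

    ``layout`` is a list of ``(center, diameter_px, kind)`` with kind in
    {"ok", "clipped", "touching"}; a "touching" entry renders a *pair* of
    disks separated by ``pair_gap_px``. The returned truth manifest lists
    every rendered disk with its expected QC outcome ("accept",
    "not_full_view", or "touching"). Overlapping "ok" spheroids are a
    layout error.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    disks = []  # (center, radius, expected)
    for center, diameter_px, kind in layout:
        radius = diameter_px / 2.0
        if kind == "ok":
            disks.append((tuple(center), radius, "accept"))
        elif kind == "clipped":
            disks.append((tuple(center), radius, "not_full_view"))
        elif kind == "touching":
            r2 = radius * 0.8
            second = (center[0], center[1] + radius + pair_gap_px + r2)
            disks.append((tuple(center), radius, "touching"))
            disks.append((second, r2, "touching"))
        else:
            raise ValueError(f"unknown layout kind {kind!r}")

    for i in range(len(disks)):
        for j in range(i + 1, len(disks)):
            (c1, r1, e1), (c2, r2, e2) = disks[i], disks[j]
            gap = np.hypot(c1[0] - c2[0], c1[1] - c2[1]) - r1 - r2
            if e1 == "accept" and e2 == "accept" and gap <= 0:
                raise ValueError(f"layout error: 'ok' spheroids {i} and {j} overlap")

    values = np.full(shape, background)
    rr, cc = np.mgrid[0:rows, 0:cols]
    for center, radius, _ in disks:
        inside = np.hypot(rr - center[0], cc - center[1]) <= radius
        values[inside] = intensity
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, shape)
    values = np.clip(values, 0.0, None)
    image = ImageGrid(values, pixel_size_um, "qc_field", 0)
    truth = [
        {"center": center, "radius_px": radius, "expected": expected}
        for center, radius, expected in disks
    ]
    return image, truth


def random_qc_layout(rng: np.random.Generator, shape: tuple[int, int] = (200, 200),
                     pad_fraction: float = 0.15):
    """Draw a random mixed layout of ok / clipped / touching spheroids.

    Placement keeps each case unambiguous for the triage defaults: "ok"
    disks clear the border by enough for their padded crop and keep >= 10
    px of clearance from every other disk; "clipped" disks overlap the
    border by at least 5 px; touching pairs sit well inside the field.
    """
    rows, cols = shape
    n_ok = int(rng.integers(1, 4))
    n_clipped = int(rng.integers(0, 2))
    n_touching = int(rng.integers(0, 2))

    placed = []  # (center, effective_radius) for clearance checks

    def clear(center, radius, min_gap=10.0):
        return all(
            np.hypot(center[0] - c[0], center[1] - c[1]) - radius - r > min_gap
            for c, r in placed
        )

    layout = []
    for _ in range(n_ok):
        for _attempt in range(200):
            radius = float(rng.uniform(12, 25))
            margin = radius * (1 + 2 * pad_fraction) + 4
            center = (float(rng.uniform(margin, rows - 1 - margin)),
                      float(rng.uniform(margin, cols - 1 - margin)))
            if clear(center, radius):
                layout.append((center, 2 * radius, "ok"))
                placed.append((center, radius))
                break
    for _ in range(n_touching):
        for _attempt in range(200):
            radius = float(rng.uniform(10, 18))
            extent = radius + 2.0 + 2 * radius * 0.8  # pair spans to the right
            margin = radius * 1.5 + 6
            center = (float(rng.uniform(margin, rows - 1 - margin)),
                      float(rng.uniform(margin, cols - 1 - extent - 8)))
            pair_center = (center[0], center[1] + radius + 2.0 + radius * 0.8)
            if clear(center, radius) and clear(pair_center, radius * 0.8):
                layout.append((center, 2 * radius, "touching"))
                placed.append((center, radius))
                placed.append((pair_center, radius * 0.8))
                break
    for _ in range(n_clipped):
        for _attempt in range(200):
            radius = float(rng.uniform(12, 22))
            edge = int(rng.integers(0, 4))
            along = float(rng.uniform(radius + 8, cols - 1 - radius - 8))
            inset = radius - float(rng.uniform(5, max(6.0, radius - 2)))
            if edge == 0:
                center = (inset, along)
            elif edge == 1:
                center = (rows - 1 - inset, along)
            elif edge == 2:
                center = (along, inset)
            else:
                center = (along, cols - 1 - inset)
            if clear(center, radius):
                layout.append((center, 2 * radius, "clipped"))
                placed.append((center, radius))
                break
    return layout


def decay_histogram(A1: float, A2: float, tau1_ns: float, tau2_ns: float,
                    photons: float, nbins: int, window_ns: float) -> np.ndarray:
    """Expected (noise-free) bin counts of the biexponential decay.

    Integrates the model over each bin and scales so the histogram sums
    to ``photons``.
    """
    if not (0 < tau1_ns < tau2_ns):
        raise ValueError("need 0 < tau1 < tau2")
    edges = np.linspace(0.0, window_ns, nbins + 1)
    def comp(a, tau):
        return a * tau * (np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau))
    expected = comp(A1, tau1_ns) + comp(A2, tau2_ns)
    return photons * expected / expected.sum()


def make_decay_stack(spec: DecayPhantomSpec):
    """Poisson-sample a decay stack from known biexponential truth.

    With ``core_params`` set, a central disk gets those parameters and the
    surrounding annulus the spec's own — a two-region spheroid phantom.
    Returns ``(DecayStack, truth)`` where truth maps each pixel to its
    generating parameters via the ``core_mask``.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    edge_curve = decay_histogram(spec.A1, spec.A2, spec.tau1_ns, spec.tau2_ns,
                                 spec.photons_per_pixel, spec.nbins,
                                 spec.window_ns)
    rr, cc = np.mgrid[0:rows, 0:cols]
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    core_mask = np.zeros((rows, cols), dtype=bool)
    curves = np.tile(edge_curve, (rows, cols, 1))
    if spec.core_params is not None:
        p = spec.core_params
        core_curve = decay_histogram(p["A1"], p["A2"], p["tau1_ns"], p["tau2_ns"],
                                     spec.photons_per_pixel, spec.nbins,
                                     spec.window_ns)
        radius = spec.core_radius_fraction * min(rows, cols) / 2.0
        core_mask = np.hypot(rr - center[0], cc - center[1]) <= radius
        curves[core_mask] = core_curve
    counts = rng.poisson(curves) if spec.photons_per_pixel > 0 else np.zeros_like(curves, dtype=np.int64)
    bin_width = spec.window_ns / spec.nbins
    stack = DecayStack(counts.astype(np.int64), bin_width, spec.pixel_size_um)
    truth = {
        "core_mask": core_mask,
        "edge_params": {"A1": spec.A1, "A2": spec.A2,
                        "tau1_ns": spec.tau1_ns, "tau2_ns": spec.tau2_ns},
        "core_params": dict(spec.core_params) if spec.core_params else None,
        "expected_edge_curve": edge_curve,
    }
    return stack, truth


def make_cohort(n_small: int, n_large: int, marker_effects: dict | None = None,
                seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Simulate per-region normalised marker values for a spheroid cohort.

    Values are drawn from Normal(mean, sd) per (marker, size class,
    region) and clipped to [0, 1]; diameters are uniform within the class
    bounds. Defaults to the reference CD80/CD206 effect sizes.
    """
    if n_small < 2 or n_large < 2:
        raise ValueError("need at least 2 spheroids per size class")
    if marker_effects is None:
        marker_effects = REFERENCE_MARKER_EFFECTS
    rng = np.random.default_rng(seed)
    rows = []
    counters = {"small": n_small, "large": n_large}
    bounds = {"small": (60.0, 200.0), "large": (201.0, 400.0)}
    sid = 0
    for size_class, n in counters.items():
        lo, hi = bounds[size_class]
        for _ in range(n):
            diameter = float(rng.uniform(lo, hi))
            for marker, effects in marker_effects.items():
                for region in ("core", "quiescent", "edge"):
                    mean, sd = effects[(size_class, region)]
                    value = float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
                    rows.append({
                        "spheroid_id": f"sph{sid:04d}",
                        "size_class": size_class,
                        "diameter_um": diameter,
                        "marker": marker,
                        "region": region,
                        "value": value,
                    })
            sid += 1
    table = pd.DataFrame(rows)
    truth = {"marker_effects": marker_effects, "bounds": bounds}
    return table, truth
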