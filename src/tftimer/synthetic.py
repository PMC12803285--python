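"""Seeded generators for pulse-chase series and wing-disc images.

The generators emulate the two measurement geometries of the tandem-timer
study of Smoothened turnover in the Drosophila wing disc:

* **Pulse-chase series** — two-channel (fast/slow chromophore) fluorescence
  of a cytoplasmic tandem timer after a 1 h expression pulse, imaged every
  15 min, with multiplicative measurement noise.

* **Disc images** — two optical sections (apical, basolateral) of a
  columnar epithelium split into posterior (P), ptc-band (the 3-4-cell
  anterior strip of high Hh response) and far-anterior regions.  The
  basolateral section carries membrane-outline signal proportional to the
  steady-state basolateral pools of the tagged protein (matured amount per
  chromophore), the apical section carries punctate signal proportional to
  the apical pools with acidic quenching applied, an Hh channel is
  partitioned between compartments, and a Rab7 channel is placed to hit
  intended Hh-Rab7 overlap fractions.  A Gaussian PSF blur and
  Poisson-Gaussian noise are applied last, and every latent quantity is
  recorded in a :class:`GroundTruth`.

Channel order is fixed: ``("fast", "slow", "hh", "rab7", "membrane")``;
section order is ``("apical", "basolateral")``.  All randomness derives
from a single integer seed.  Intensities are arbitrary units (the study
reports only ratios and fractions), lengths are micrometres, times hours.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from .kinetics import (
    FLUOROPHORES,
    FluorophorePair,
    TraffickingParams,
    pulse_matured_fraction,
    simulate_trafficking,
    steady_state_pools,
)

__all__ = [
    "CHANNELS",
    "SECTIONS",
    "DiscGeometry",
    "NoiseModel",
    "ScenarioConfig",
    "GroundTruth",
    "DiscImage",
    "PulseSeries",
    "GeneratorError",
    "CapacityError",
    "generate_pulse_series",
    "generate_disc_image",
    "scenario_preset",
    "PRESETS",
]

CHANNELS = ("fast", "slow", "hh", "rab7", "membrane")
SECTIONS = ("apical", "basolateral")

#: base region labels, anterior to posterior
REGIONS = ("far_A", "ptc_band", "P")


class GeneratorError(ValueError):
    pass


class CapacityError(GeneratorError):
    """Geometry too small to place the requested puncta."""


@dataclass(frozen=True)
class DiscGeometry:
    """Layout of the synthetic wing-disc field.

    x increases anterior -> posterior; the ptc band is the strip of
    ``ptc_band_width`` cells immediately anterior to ``boundary_x``.
    Masks use 0-based, half-open pixel indexing.
    """

    cell_diameter: float = 2.5        # um
    ptc_band_width: int = 3           # cells, 3 or 4
    field_width: float = 60.0         # um, along A/P axis
    field_height: float = 60.0        # um
    boundary_x: float = 30.0          # um, A/P compartment boundary
    pixel_size: float = 0.2           # um / px

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise GeneratorError("pixel_size must be > 0")
        if self.ptc_band_width not in (3, 4):
            raise GeneratorError(
                f"ptc_band_width must be 3 or 4 cells, got {self.ptc_band_width}"
            )
        if not (0 < self.boundary_x < self.field_width):
            raise GeneratorError("boundary_x must lie inside the field")
        if self.band_start_x <= 0:
            raise GeneratorError("ptc band does not fit anterior to the boundary")

    @property
    def band_start_x(self) -> float:
        return self.boundary_x - self.ptc_band_width * self.cell_diameter

    @property
    def shape(self) -> tuple:
        return (
            int(round(self.field_height / self.pixel_size)),
            int(round(self.field_width / self.pixel_size)),
        )

    def x_um(self) -> np.ndarray:
        """Column-centre positions along the A/P axis."""
        nx = self.shape[1]
        return (np.arange(nx) + 0.5) * self.pixel_size

    def region_masks(self, split_dorsal: bool = False) -> dict:
        """Boolean masks partitioning the field into labelled regions."""
        ny, nx = self.shape
        x = self.x_um()[None, :] * np.ones((ny, 1))
        base = {
            "far_A": x < self.band_start_x,
            "ptc_band": (x >= self.band_start_x) & (x < self.boundary_x),
            "P": x >= self.boundary_x,
        }
        if not split_dorsal:
            return base
        y = (np.arange(ny) + 0.5)[:, None] * self.pixel_size * np.ones((1, nx))
        dorsal = y >= self.field_height / 2.0
        out = {}
        for label, m in base.items():
            out[f"{label}_dorsal"] = m & dorsal
            out[f"{label}_ventral"] = m & ~dorsal
        return out

    def ap_masks(self) -> dict:
        masks = self.region_masks(split_dorsal=False)
        return {"A": masks["far_A"] | masks["ptc_band"], "P": masks["P"]}

    def membrane_mask(self) -> np.ndarray:
        """Cell-outline lattice on a hexagonal-ish grid of cell centres."""
        ny, nx = self.shape
        d = self.cell_diameter / self.pixel_size
        row_step = d * np.sqrt(3.0) / 2.0
        centers = []
        yc = 0.0
        row = 0
        while yc < ny + d:
            offset = 0.0 if row % 2 == 0 else d / 2.0
            xc = offset
            while xc < nx + d:
                centers.append((yc, xc))
                xc += d
            yc += row_step
            row += 1
        tree = cKDTree(np.asarray(centers))
        yy, xx = np.mgrid[0:ny, 0:nx]
        _, labels = tree.query(np.column_stack([yy.ravel(), xx.ravel()]))
        label_img = labels.reshape(ny, nx)
        return find_boundaries(label_img, mode="thick")


@dataclass(frozen=True)
class NoiseModel:
    """Poisson-Gaussian detector model.

    A pixel with noiseless mean ``v`` is reported as
    ``Poisson((v + background) * poisson_scale) / poisson_scale
    + Normal(0, gaussian_sd)`` so per-pixel variance grows linearly with
    the mean (shot noise) on top of a constant read-noise floor.
    """

    poisson_scale: float = 4.0
    gaussian_sd: float = 0.5
    background: float = 2.0

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        v = clean + self.background
        if self.poisson_scale > 0:
            v = rng.poisson(v * self.poisson_scale) / self.poisson_scale
        if self.gaussian_sd > 0:
            v = v + rng.normal(0.0, self.gaussian_sd, size=v.shape)
        return v


@dataclass
class ScenarioConfig:
    """Everything needed to generate one synthetic disc deterministically."""

    name: str = "wild_type"
    geometry: DiscGeometry = field(default_factory=DiscGeometry)
    region_params: Mapping[str, TraffickingParams] = field(default_factory=dict)
    fluorophores: FluorophorePair = field(
        default_factory=FluorophorePair.from_half_times
    )
    hh_partition: float = 0.95        # fraction of Hh-channel signal in P
    overlap_aA: float = 0.85          # intended apical A-compartment Hh-Rab7 overlap
    overlap_aP: float = 0.50          # same for P
    # puncta geometry / amplitudes (arbitrary units)
    puncta_radius_um: float = 0.4     # Gaussian sigma of Hh and Smo spots
    rab7_radius_um: float = 0.65
    smo_puncta_density: float = 0.03  # puncta per um^2 per region, apical
    smo_punctum_scale: float = 2.0e4  # integrated intensity per unit pool amount
    membrane_brightness: float = 200.0  # intensity per unit matured amount
    hh_total: float = 5.0e7           # integrated Hh intensity per section
    n_hh_apical_A: int = 40
    n_hh_apical_P: int = 160
    n_hh_basolateral_A: int = 20
    rab7_amplitude: float = 3.0e4     # integrated intensity per Rab7 punctum
    psf_sigma_um: float = 0.15
    noise: NoiseModel | None = field(default_factory=NoiseModel)
    nh4cl: bool = False               # neutralize acidic quenching
    split_dorsal: bool = False
    transient_hours: float | None = None
    initial_region_params: Mapping[str, TraffickingParams] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("hh_partition", "overlap_aA", "overlap_aP"):
            v = getattr(self, nm)
            if not (0.0 <= v <= 1.0):
                raise GeneratorError(f"{nm} must lie in [0, 1], got {v}")

    def effective_pair(self) -> FluorophorePair:
        return self.fluorophores.neutralized() if self.nh4cl else self.fluorophores

    def pools(self) -> dict:
        """Latent pool amounts per region (steady state or transient)."""
        out = {}
        for label, params in self.region_params.items():
            if self.transient_hours is None:
                out[label] = steady_state_pools(params, self.fluorophores)
            else:
                init_params = (self.initial_region_params or self.region_params)[label]
                init = steady_state_pools(init_params, self.fluorophores)
                traj = simulate_trafficking(
                    params,
                    self.fluorophores,
                    np.array([0.0, self.transient_hours]),
                    initial=init,
                )
                out[label] = traj.state_at(-1)
        return out


@dataclass
class DiscImage:
    """Multichannel two-section intensity grids (C, Y, X per section)."""

    sections: dict
    channels: tuple = CHANNELS
    pixel_size: float = 0.2
    meta: dict = field(default_factory=dict)

    def channel(self, section: str, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"unknown channel {name!r}; expected one of {self.channels}")
        if section not in self.sections:
            raise KeyError(f"unknown section {section!r}")
        return self.sections[section][self.channels.index(name)]


@dataclass
class GroundTruth:
    """Generator-known latents for recovery tests."""

    region_masks: dict
    ap_masks: dict
    membrane_mask: np.ndarray
    puncta: pd.DataFrame
    pools: dict
    residence_times: dict
    partition_intended: float
    partition_realized: float
    overlap_intended: dict
    overlap_realized: dict
    clean: dict
    scenario: ScenarioConfig


@dataclass
class PulseSeries:
    """Replicated two-channel pulse-chase measurements plus their truth."""

    times: np.ndarray
    signals: np.ndarray          # (n_replicates, 2, n_times), fast then slow
    noiseless: np.ndarray        # (2, n_times)
    pair: FluorophorePair
    pulse_duration: float
    noise_cv: float
    seed: int

    channel_order = ("fast", "slow")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.signals.shape[0]):
            for ci, ch in enumerate(self.channel_order):
                for ti, t in enumerate(self.times):
                    rows.append((r, ch, float(t), float(self.signals[r, ci, ti])))
        return pd.DataFrame(rows, columns=["replicate", "channel", "time_h", "signal"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PulseSeries":
        times = np.sort(frame["time_h"].unique())
        reps = np.sort(frame["replicate"].unique())
        signals = np.empty((len(reps), 2, len(times)))
        for ri, r in enumerate(reps):
            for ci, ch in enumerate(cls.channel_order):
                sub = frame[(frame.replicate == r) & (frame.channel == ch)]
                if len(sub) != len(times):
                    raise GeneratorError(
                        f"replicate {r} channel {ch}: expected {len(times)} rows"
                    )
                signals[ri, ci] = sub.sort_values("time_h")["signal"].to_numpy()
        pair = FluorophorePair.from_half_times()
        return cls(
            times=times, signals=signals, noiseless=np.full((2, len(times)), np.nan),
            pair=pair, pulse_duration=1.0, noise_cv=np.nan, seed=-1,
        )


def generate_pulse_series(
    pair: FluorophorePair | None = None,
    pulse_duration: float = 1.0,
    times=None,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    lag: float = 0.0,
) -> PulseSeries:
    """Two-channel pulse-chase series under first-order maturation.

    The noiseless mean of each channel is the pulse-model matured fraction;
    replicates differ only by multiplicative Gaussian noise of coefficient
    of variation ``noise_cv``.  The default grid (0-12 h, 15-min steps)
    matches the calibration experiment's imaging cadence.
    """
    if pair is None:
        pair = FluorophorePair.from_half_times()
    if noise_cv < 0:
        raise GeneratorError(f"noise_cv must be >= 0, got {noise_cv}")
    if times is None:
        times = np.arange(0.0, 12.0 + 1e-9, 0.25)
    times = np.asarray(times, dtype=float)
    clean = np.vstack(
        [
            pulse_matured_fraction(times, pulse_duration, pair.m_fast, lag=lag),
            pulse_matured_fraction(times, pulse_duration, pair.m_slow, lag=lag),
        ]
    )
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=(n_replicates,) + clean.shape)
    signals = clean[None, :, :] * (1.0 + noise_cv * noise)
    return PulseSeries(
        times=times, signals=signals, noiseless=clean, pair=pair,
        pulse_duration=pulse_duration, noise_cv=noise_cv, seed=seed,
    )


# ---------------------------------------------------------------------------
# Disc image generation
# ---------------------------------------------------------------------------

def _place_points(
    rng: np.random.Generator,
    n: int,
    region_mask: np.ndarray,
    pixel_size: float,
    min_sep_px: float,
    avoid: np.ndarray | None = None,
    avoid_sep_px: float = 0.0,
    edge_margin_px: float = 8.0,
    boundary_cols=(),
    boundary_margin_px: float = 5.0,
    max_tries: int = 4000,
) -> np.ndarray:
    """Rejection-sample n punctum centres (row, col) inside a region mask.

    Enforces a minimum pairwise separation within the new set and, if
    ``avoid`` is given, a separation from those points too.  Raises
    :class:`CapacityError` when the geometry cannot host the request.
    """
    ny, nx = region_mask.shape
    rows, cols = np.nonzero(region_mask)
    ok = (
        (rows >= edge_margin_px) & (rows < ny - edge_margin_px)
        & (cols >= edge_margin_px) & (cols < nx - edge_margin_px)
    )
    for bc in boundary_cols:
        ok &= np.abs(cols - bc) >= boundary_margin_px
    rows, cols = rows[ok], cols[ok]
    if rows.size == 0:
        raise CapacityError("region has no admissible pixels for puncta")
    placed: list = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries * max(n, 1):
            raise CapacityError(
                f"could not place {n} puncta with min separation "
                f"{min_sep_px * pixel_size:.2f} um; geometry too small"
            )
        i = rng.integers(rows.size)
        cand = np.array([rows[i] + rng.uniform(-0.5, 0.5),
                         cols[i] + rng.uniform(-0.5, 0.5)])
        if placed:
            d = np.linalg.norm(np.asarray(placed) - cand, axis=1)
            if d.min() < min_sep_px:
                continue
        if avoid is not None and avoid.size:
            d = np.linalg.norm(avoid - cand, axis=1)
            if d.min() < avoid_sep_px:
                continue
        placed.append(cand)
    return np.asarray(placed).reshape(n, 2)


def _render_spots(canvas: np.ndarray, centers: np.ndarray, sigmas_px, amplitudes) -> None:
    """Accumulate Gaussian spots (integrated intensity = amplitude) in place."""
    ny, nx = canvas.shape
    sigmas_px = np.broadcast_to(np.asarray(sigmas_px, dtype=float), (len(centers),))
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(centers),))
    for (r, c), s, a in zip(centers, sigmas_px, amplitudes):
        if a == 0:
            continue
        w = int(np.ceil(4 * s))
        r0, r1 = max(0, int(r) - w), min(ny, int(r) + w + 1)
        c0, c1 = max(0, int(c) - w), min(nx, int(c) + w + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        g = np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * s * s))
        canvas[r0:r1, c0:c1] += a / (2 * np.pi * s * s) * g


def _base_label(label: str) -> str:
    for b in REGIONS:
        if label.startswith(b):
            return b
    raise GeneratorError(f"region label {label!r} does not extend a known region")


def generate_disc_image(scenario: ScenarioConfig):
    """Render one synthetic disc; returns ``(DiscImage, GroundTruth)``.

    Deterministic given ``scenario.seed``.  The basolateral section draws
    membrane-outline signal proportional to each region's basolateral
    matured amounts; the apical section draws Smo puncta proportional to
    apical pools (with acidic quenching unless ``nh4cl``), Hh puncta split
    ``hh_partition`` : ``1 - hh_partition`` between P and A, and Rab7
    puncta paired with Hh puncta to realize the intended overlap fractions.
    """
    geom = scenario.geometry
    ny, nx = geom.shape
    px = geom.pixel_size
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    region_masks = geom.region_masks(split_dorsal=scenario.split_dorsal)
    if set(scenario.region_params) != set(region_masks):
        raise GeneratorError(
            f"region_params keys {sorted(scenario.region_params)} do not match "
            f"geometry regions {sorted(region_masks)}"
        )
    ap = geom.ap_masks()
    membrane = geom.membrane_mask()
    pools = scenario.pools()
    pair = scenario.fluorophores
    sigma_px = scenario.puncta_radius_um / px
    rab_sigma_px = scenario.rab7_radius_um / px
    psf_px = scenario.psf_sigma_um / px
    boundary_col = geom.boundary_x / px

    clean = {s: np.zeros((len(CHANNELS), ny, nx)) for s in SECTIONS}
    ci = {name: i for i, name in enumerate(CHANNELS)}
    puncta_rows = []
    pair_counter = 0

    def region_of(point) -> str:
        r, c = int(point[0]), int(point[1])
        for label, m in region_masks.items():
            if m[r, c]:
                return label
        return ""

    # ---- membrane channel (both sections) and basolateral membrane pools
    for s in SECTIONS:
        clean[s][ci["membrane"]][membrane] = 100.0
    for label, m in region_masks.items():
        on = membrane & m
        st = pools[label]
        clean["basolateral"][ci["fast"]][on] = (
            scenario.membrane_brightness * st.B_mat["fast"]
        )
        clean["basolateral"][ci["slow"]][on] = (
            scenario.membrane_brightness * st.B_mat["slow"]
        )

    # ---- apical Smo puncta: per-region pools split over puncta
    q = {
        f: pair.quench(f, acidic=True, nh4cl=scenario.nh4cl)
        for f in FLUOROPHORES
    }
    for label, m in region_masks.items():
        area_um2 = m.sum() * px * px
        n = max(1, int(round(scenario.smo_puncta_density * area_um2)))
        pts = _place_points(
            rng, n, m, px, min_sep_px=2.0 / px,
            boundary_cols=(boundary_col,),
        )
        st = pools[label]
        amp = {f: scenario.smo_punctum_scale * q[f] * st.E_mat[f] for f in FLUOROPHORES}
        for f in FLUOROPHORES:
            _render_spots(clean["apical"][ci[f]], pts, sigma_px, amp[f])
        for p in pts:
            puncta_rows.append(
                dict(section="apical", kind="smo", region=label,
                     y_um=p[0] * px, x_um=p[1] * px, sigma_um=scenario.puncta_radius_um,
                     amp_fast=amp["fast"], amp_slow=amp["slow"], amp_hh=0.0,
                     amp_rab7=0.0, pair_id=-1)
            )

    # ---- Hh + Rab7, apical section, per compartment
    hh_sect_total = scenario.hh_total
    comp_cfg = {
        "A": dict(mask=ap["A"], n=scenario.n_hh_apical_A,
                  total=(1.0 - scenario.hh_partition) * hh_sect_total,
                  overlap=scenario.overlap_aA,
                  unpaired_rab=max(1, round(0.2 * scenario.n_hh_apical_A)),
                  rab_excl_px=2.8 / px),
        "P": dict(mask=ap["P"], n=scenario.n_hh_apical_P,
                  total=scenario.hh_partition * hh_sect_total,
                  overlap=scenario.overlap_aP,
                  unpaired_rab=max(1, round(0.05 * scenario.n_hh_apical_P)),
                  rab_excl_px=1.5 / px),
    }
    overlap_intended, overlap_realized = {}, {}
    for comp, cfg in comp_cfg.items():
        n = cfg["n"]
        pts = _place_points(
            rng, n, cfg["mask"], px, min_sep_px=2.0 / px,
            boundary_cols=(boundary_col,),
        )
        amp = cfg["total"] / n
        n_paired = int(round(cfg["overlap"] * n))
        paired_idx = rng.permutation(n)[:n_paired]
        is_paired = np.zeros(n, dtype=bool)
        is_paired[paired_idx] = True
        _render_spots(clean["apical"][ci["hh"]], pts, sigma_px, amp)
        _render_spots(
            clean["apical"][ci["rab7"]], pts[is_paired], rab_sigma_px,
            scenario.rab7_amplitude,
        )
        for i, p in enumerate(pts):
            pid = -1
            if is_paired[i]:
                pid = pair_counter
                pair_counter += 1
                puncta_rows.append(
                    dict(section="apical", kind="rab7", region=region_of(p),
                         y_um=p[0] * px, x_um=p[1] * px,
                         sigma_um=scenario.rab7_radius_um,
                         amp_fast=0.0, amp_slow=0.0, amp_hh=0.0,
                         amp_rab7=scenario.rab7_amplitude, pair_id=pid)
                )
            puncta_rows.append(
                dict(section="apical", kind="hh", region=region_of(p),
                     y_um=p[0] * px, x_um=p[1] * px, sigma_um=scenario.puncta_radius_um,
                     amp_fast=0.0, amp_slow=0.0, amp_hh=amp, amp_rab7=0.0,
                     pair_id=pid)
            )
        # unpaired Rab7, kept away from Hh puncta so realized overlap stays
        # within 0.02 of intended
        upts = _place_points(
            rng, cfg["unpaired_rab"], cfg["mask"], px, min_sep_px=2.0 / px,
            avoid=pts, avoid_sep_px=cfg["rab_excl_px"],
            boundary_cols=(boundary_col,),
        )
        _render_spots(
            clean["apical"][ci["rab7"]], upts, rab_sigma_px, scenario.rab7_amplitude
        )
        for p in upts:
            puncta_rows.append(
                dict(section="apical", kind="rab7", region=region_of(p),
                     y_um=p[0] * px, x_um=p[1] * px, sigma_um=scenario.rab7_radius_um,
                     amp_fast=0.0, amp_slow=0.0, amp_hh=0.0,
                     amp_rab7=scenario.rab7_amplitude, pair_id=-1)
            )
        overlap_intended[comp] = cfg["overlap"]
        overlap_realized[comp] = n_paired / n

    # ---- Hh, basolateral section: membrane-associated in P, puncta in A
    p_membrane = membrane & ap["P"]
    clean["basolateral"][ci["hh"]][p_membrane] += (
        scenario.hh_partition * hh_sect_total / max(p_membrane.sum(), 1)
    )
    bl_pts = _place_points(
        rng, scenario.n_hh_basolateral_A, ap["A"], px, min_sep_px=2.0 / px,
        boundary_cols=(boundary_col,),
    )
    bl_amp = (1.0 - scenario.hh_partition) * hh_sect_total / scenario.n_hh_basolateral_A
    _render_spots(clean["basolateral"][ci["hh"]], bl_pts, sigma_px, bl_amp)
    for p in bl_pts:
        puncta_rows.append(
            dict(section="basolateral", kind="hh", region=region_of(p),
                 y_um=p[0] * px, x_um=p[1] * px, sigma_um=scenario.puncta_radius_um,
                 amp_fast=0.0, amp_slow=0.0, amp_hh=bl_amp, amp_rab7=0.0, pair_id=-1)
        )

    # ---- PSF blur, then noise
    for s in SECTIONS:
        for c in range(len(CHANNELS)):
            clean[s][c] = gaussian_filter(clean[s][c], psf_px, mode="nearest")
    if scenario.noise is not None:
        sections = {
            s: scenario.noise.apply(clean[s], rng).astype(np.float32)
            for s in SECTIONS
        }
    else:
        sections = {s: clean[s].astype(np.float32) for s in SECTIONS}

    apical_hh = clean["apical"][ci["hh"]]
    realized_partition = float(apical_hh[ap["P"]].sum() / apical_hh.sum())
    image = DiscImage(
        sections=sections, channels=CHANNELS, pixel_size=px,
        meta=dict(
            scenario=scenario.name, seed=scenario.seed,
            channels=list(CHANNELS), sections=list(SECTIONS),
            nh4cl=scenario.nh4cl,
        ),
    )
    truth = GroundTruth(
        region_masks=region_masks,
        ap_masks=ap,
        membrane_mask=membrane,
        puncta=pd.DataFrame(puncta_rows),
        pools=pools,
        residence_times={
            label: p.residence_time for label, p in scenario.region_params.items()
        },
        partition_intended=scenario.hh_partition,
        partition_realized=realized_partition,
        overlap_intended=overlap_intended,
        overlap_realized=overlap_realized,
        clean=clean,
        scenario=scenario,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _params(tau_by_region: Mapping[str, float], sigma=1.0, k_deg=0.5) -> dict:
    return {
        label: TraffickingParams.from_residence_time(
            tau, sigma=sigma, k_deg=k_deg, region_label=label
        )
        for label, tau in tau_by_region.items()
    }


#: wild-type basolateral residence times (hours).  Chosen so that the
#: steady-state membrane ratios, read back through the default 1 h pulse
#: calibration curve, land at the study's regional readouts (~8 h posterior,
#: ~4 h ptc band, ~1.7 h far anterior, a roughly two-fold Hh-dependent
#: contrast); the latent mean residences themselves are shorter because a
#: constitutively synthesized pool carries an exponential age mixture.
WILD_TYPE_TAU = {"P": 6.0, "ptc_band": 2.2, "far_A": 0.7}

PRESETS = (
    "wild_type", "disp_mutant", "hh_cd2", "usp8_dorsal", "nh4cl",
    "uniform_turnover",
)


def scenario_preset(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Named study conditions.

    wild_type         three regions with Hh-graded basolateral residence
                      (P > ptc_band > far_A)
    disp_mutant       Hh transport from P blocked: all anterior regions take
                      the short far-anterior residence
    hh_cd2            membrane-tethered Hh overexpressed: anterior residence
                      raised toward posterior-like values
    usp8_dorsal       Smo degradation reduced dorsally: dorsal k_exit halved,
                      rendered 6 h into the transient from the wild-type
                      steady state
    nh4cl             wild type imaged in ammonium chloride (acidic quenching
                      neutralized)
    uniform_turnover  identical trafficking everywhere (the uniform-turnover
                      null: regions are indistinguishable)
    """
    if name not in PRESETS:
        raise GeneratorError(f"unknown preset {name!r}; choose from {PRESETS}")
    kw: dict = dict(name=name, seed=seed)
    if name == "wild_type":
        kw["region_params"] = _params(WILD_TYPE_TAU)
    elif name == "disp_mutant":
        kw["region_params"] = _params(
            {"P": WILD_TYPE_TAU["P"], "ptc_band": 0.7, "far_A": 0.7}
        )
    elif name == "hh_cd2":
        kw["region_params"] = _params(
            {"P": WILD_TYPE_TAU["P"], "ptc_band": 4.5, "far_A": 3.0}
        )
    elif name == "nh4cl":
        kw["region_params"] = _params(WILD_TYPE_TAU)
        kw["nh4cl"] = True
    elif name == "uniform_turnover":
        kw["region_params"] = _params(
            {label: 3.0 for label in ("P", "ptc_band", "far_A")}
        )
    elif name == "usp8_dorsal":
        kw["split_dorsal"] = True
        wt, pert = {}, {}
        for label, tau in WILD_TYPE_TAU.items():
            for half in ("dorsal", "ventral"):
                wt[f"{label}_{half}"] = tau
                pert[f"{label}_{half}"] = 2.0 * tau if half == "dorsal" else tau
        kw["region_params"] = _params(pert)
        kw["initial_region_params"] = _params(wt)
        kw["transient_hours"] = 6.0
    kw.update(overrides)
    return ScenarioConfig(**kw)


def scenario_to_dict(s: ScenarioConfig) -> dict:
    """Plain-dict form of a scenario for YAML round-tripping."""
    d: dict = dict(
        name=s.name, seed=int(s.seed), nh4cl=bool(s.nh4cl),
        split_dorsal=bool(s.split_dorsal),
        hh_partition=s.hh_partition, overlap_aA=s.overlap_aA,
        overlap_aP=s.overlap_aP,
        puncta_radius_um=s.puncta_radius_um, rab7_radius_um=s.rab7_radius_um,
        smo_puncta_density=s.smo_puncta_density,
        smo_punctum_scale=s.smo_punctum_scale,
        membrane_brightness=s.membrane_brightness, hh_total=s.hh_total,
        n_hh_apical_A=s.n_hh_apical_A, n_hh_apical_P=s.n_hh_apical_P,
        n_hh_basolateral_A=s.n_hh_basolateral_A,
        rab7_amplitude=s.rab7_amplitude, psf_sigma_um=s.psf_sigma_um,
        transient_hours=s.transient_hours,
        geometry=dataclasses.asdict(s.geometry),
        fluorophores=dict(
            m_fast=s.fluorophores.m_fast, m_slow=s.fluorophores.m_slow,
            q_fast_acidic=s.fluorophores.q_fast_acidic,
            q_slow_acidic=s.fluorophores.q_slow_acidic,
        ),
        regions={
            label: dict(sigma=p.sigma, k_exit=p.k_exit, k_deg=p.k_deg)
            for label, p in s.region_params.items()
        },
        noise=None if s.noise is None else dataclasses.asdict(s.noise),
    )
    if s.initial_region_params is not None:
        d["initial_regions"] = {
            label: dict(sigma=p.sigma, k_exit=p.k_exit, k_deg=p.k_deg)
            for label, p in s.initial_region_params.items()
        }
    return d


def scenario_from_dict(d: Mapping) -> ScenarioConfig:
    d = dict(d)
    geometry = DiscGeometry(**d.pop("geometry", {}))
    fl = d.pop("fluorophores", None)
    pair = FluorophorePair(**fl) if fl else FluorophorePair.from_half_times()
    regions = {
        label: TraffickingParams(region_label=label, **p)
        for label, p in d.pop("regions", {}).items()
    }
    init = d.pop("initial_regions", None)
    noise = d.pop("noise", "missing")
    kw = dict(d)
    kw["geometry"] = geometry
    kw["fluorophores"] = pair
    kw["region_params"] = regions
    if init is not None and init != "missing":
        kw["initial_region_params"] = {
            label: TraffickingParams(region_label=label, **p)
            for label, p in init.items()
        }
    if noise != "missing":
        kw["noise"] = None if noise is None else NoiseModel(**noise)
    return ScenarioConfig(**kw)
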