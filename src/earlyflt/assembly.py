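"""Measurement-array and sensitivity-matrix assembly strategies.

With three source–detector distances R1 > R2 > R3 and gated measurements,
each FPDF reconstruction is tied to one average photon velocity v = R/t.
Strategy 1 uses a single gate t for all three distances, giving three
single-distance systems with velocities R_m/t.  Strategy 2 assigns each
distance its own gate so that R/t is constant within a reconstruction
(t_m = R_m/R_ref · t_ref), letting two or three distances contribute rows
to the same system and raising the row count J per reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mc import SensitivityVolume
from .phantom import ScanPattern, SRLink, VoxelGrid


class AssemblyError(ValueError):
    """Missing or inconsistent inputs while assembling a linear system."""


@dataclass(frozen=True)
class StrategyEntry:
    """One FPDF reconstruction: the SR distances used, the gate assigned to
    each (ps), the common velocity R/t (mm/ps) and the expected row count."""

    used_sr_distances: tuple[float, ...]
    gate_per_distance: dict[float, int]
    velocity: float
    expected_links: int
    exact_gates: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for R in self.used_sr_distances:
            t_exact = self.exact_gates.get(R, self.gate_per_distance[R])
            if abs(R / t_exact - self.velocity) > 1e-9:
                raise AssemblyError("R/t must equal the entry velocity")


@dataclass(frozen=True)
class Strategy:
    entries: tuple[StrategyEntry, ...]

    def __post_init__(self) -> None:
        v = [e.velocity for e in self.entries]
        if len(set(v)) != len(v):
            raise AssemblyError("entry velocities must be pairwise distinct")

    @property
    def velocities(self) -> tuple[float, ...]:
        return tuple(e.velocity for e in self.entries)


@dataclass
class LinearSystem:
    """The assembled W f = g system for one FPDF reconstruction.

    ``W`` is J×I with rows equal to flattened sensitivity volumes (relative
    units); ``g`` holds the matching gated measurements times the global
    calibration scalar.  ``rows`` records (link key, gate) per row;
    ``grid`` is the reconstruction ROI the columns refer to.
    """

    W: np.ndarray
    g: np.ndarray
    grid: VoxelGrid
    rows: list[tuple] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.W.shape[0] != len(self.g):
            raise AssemblyError("row count of W must equal len(g)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.W.shape


def build_strategy1(sr_distances, gate: float, n_positions: int = 361
                    ) -> Strategy:
    """One entry per SR distance, all sharing a single gate; velocities
    R/t differ across entries."""
    ds = tuple(float(R) for R in sr_distances)
    if len(set(ds)) != len(ds):
        raise AssemblyError("sr_distances must be distinct")
    if gate <= 0:
        raise AssemblyError("gate must be > 0")
    entries = []
    for R in ds:
        entries.append(StrategyEntry(
            used_sr_distances=(R,),
            gate_per_distance={R: int(gate)},
            velocity=R / gate,
            expected_links=n_positions,
            exact_gates={R: float(gate)}))
    return Strategy(entries=tuple(entries))


def build_strategy2(sr_distances, base_gate: float, n_positions: int = 361
                    ) -> Strategy:
    """Constant-velocity entries over two or three distances.

    With distances R1 > R2 > R3 and ``base_gate`` the maximum admissible
    gate: entry 1 uses all three distances at gates t_m = R_m/R1·base_gate
    (v = R1/base_gate); entry 2 drops R1 (whose matched gate would exceed
    base_gate) and uses R2, R3 at gates {base_gate, R3/R2·base_gate}
    (v = R2/base_gate); entry 3 drops R3 (whose matched gate would fall
    into the noisy earliest times) and uses R1, R2 at gates
    {R3/R2·base_gate, R3/R1·base_gate} (v = R1R2/(R3·base_gate)).
    Per-distance gates are truncated to whole ps as quoted for the
    reference configuration (133.33 → 133, 66.67 → 66); the exact values
    are kept in ``exact_gates``.
    """
    ds = sorted((float(R) for R in sr_distances), reverse=True)
    if len(ds) != 3 or len(set(ds)) != 3:
        raise AssemblyError("strategy 2 needs exactly three distinct distances")
    if base_gate <= 0:
        raise AssemblyError("base_gate must be > 0")
    R1, R2, R3 = ds
    t1 = float(base_gate)

    def entry(used, t_ref_R, t_ref):
        v = t_ref_R / t_ref
        exact = {R: R / v for R in used}
        # truncate to whole ps (133.33 -> 133, 66.67 -> 66); the tiny offset
        # only absorbs float dust on exact integers
        gates = {R: int(exact[R] + 1e-6) for R in used}
        return StrategyEntry(used_sr_distances=tuple(used),
                             gate_per_distance=gates, velocity=v,
                             expected_links=n_positions * len(used),
                             exact_gates=exact)

    e1 = entry((R1, R2, R3), R1, t1)           # v = R1/t1
    e2 = entry((R2, R3), R2, t1)               # v = R2/t1
    e3 = entry((R1, R2), R1, R3 / R2 * t1)     # v = R1/(R3/R2·t1)
    return Strategy(entries=(e1, e2, e3))


def replicate_rows(volumes: list[SensitivityVolume], pattern: ScanPattern,
                   source_row: int, target_row: int,
                   nearest: bool = False) -> list[SensitivityVolume]:
    """Translate sensitivity volumes computed for one scan row to another.

    Valid for a laterally translation-invariant background: shifting the
    probe by whole scan rows shifts the sensitivity volume by the same
    offset along the row axis (y).  The offset must be a whole number of
    voxels unless ``nearest`` rounding is enabled.
    """
    out = []
    for vol in volumes:
        h = vol.grid.voxel_size
        dy = (target_row - source_row) * pattern.step
        shift = dy / h
        if abs(shift - round(shift)) > 1e-9 and not nearest:
            raise AssemblyError(
                f"row shift {dy} mm is not a whole number of voxels")
        s = int(round(shift))
        values = np.zeros_like(vol.values)
        if s >= 0:
            if s < vol.values.shape[1]:
                values[:, s:, :] = vol.values[:, :vol.values.shape[1] - s, :]
        else:
            if -s < vol.values.shape[1]:
                values[:, :s, :] = vol.values[:, -s:, :]
        link = vol.link
        src = (link.source_center[0], link.source_center[1] + dy, 0.0)
        det = (link.detector_center[0], link.detector_center[1] + dy, 0.0)
        out.append(SensitivityVolume(
            grid=vol.grid, values=values,
            link=SRLink(src, det, link.sr_distance, target_row,
                        link.col_index),
            gate=vol.gate, n_histories=vol.n_histories, seed=vol.seed,
            meta=dict(vol.meta, replicated_from_row=source_row)))
    return out


def translate_volume(vol: SensitivityVolume, link: SRLink,
                     nearest: bool = False) -> SensitivityVolume:
    """Translate a sensitivity volume to another link of the same SR
    distance by the whole-voxel (x, y) surface offset between them
    ('symmetric' assembly mode: one centered kernel reused for every link)."""
    if abs(link.sr_distance - vol.link.sr_distance) > 1e-9:
        raise AssemblyError("translate_volume requires equal SR distances")
    h = vol.grid.voxel_size
    shifts = []
    for axis in (0, 1):
        d = link.source_center[axis] - vol.link.source_center[axis]
        s = d / h
        if abs(s - round(s)) > 1e-9 and not nearest:
            raise AssemblyError("link offset is not a whole number of voxels")
        shifts.append(int(round(s)))
    values = vol.values
    for axis, s in enumerate(shifts):
        values = np.roll(values, s, axis=axis)
        # zero-fill the wrapped slab
        idx = [slice(None)] * 3
        if s > 0:
            idx[axis] = slice(0, s)
        elif s < 0:
            idx[axis] = slice(s, None)
        if s != 0:
            values = values.copy()
            values[tuple(idx)] = 0.0
    return SensitivityVolume(grid=vol.grid, values=values, link=link,
                             gate=vol.gate, n_histories=vol.n_histories,
                             seed=vol.seed,
                             meta=dict(vol.meta, translated=True))


def symmetric_sensitivities(kernels: dict, links: list[SRLink],
                            amplitude: float = 1.0,
                            nearest: bool = False) -> dict:
    """'Symmetric' assembly mode: one centered kernel per SR distance and
    gate, translated to every link of that distance and scaled by a
    configured amplitude factor.

    ``kernels`` maps ``(sr_distance, gate)`` to a centered
    SensitivityVolume.  This discards the dependence of the sensitivity
    on the relative position of probe and inclusion — the no-prior
    variant of system formation — at the price of some reconstruction
    quality.
    """
    out = {}
    for link in links:
        for (R, gate), vol in kernels.items():
            if abs(link.sr_distance - R) > 1e-9:
                continue
            moved = translate_volume(vol, link, nearest=nearest)
            moved.values = moved.values * amplitude
            moved.meta["amplitude_factor"] = amplitude
            out[(link.key, int(gate))] = moved
    return out


def assemble(entry: StrategyEntry, links: list[SRLink],
             sensitivities: dict, measurements: dict,
             calibration=1.0, roi=None) -> LinearSystem:
    """Assemble W and g for one strategy entry.

    ``links`` fixes the row order (zigzag scan order; within a position,
    distance order follows the link list).  ``sensitivities`` and
    ``measurements`` are keyed by ``(link.key, gate)`` with gate the whole-ps
    value from ``entry.gate_per_distance``.  ``roi`` optionally restricts
    the columns to a subvolume given as an index tuple of slices.
    ``calibration`` is either one global scalar or a mapping
    ``(sr_distance, gate) → scalar`` (per-gate-class calibration).
    """
    used = {round(R, 6) for R in entry.used_sr_distances}
    rows_W = []
    rows_g = []
    rows_meta = []
    grid = None
    roi_shape = None
    for link in links:
        if round(link.sr_distance, 6) not in used:
            continue
        gate = entry.gate_per_distance[link.sr_distance]
        key = (link.key, gate)
        if key not in sensitivities or key not in measurements:
            raise AssemblyError(f"missing sensitivity or measurement for {key}")
        vol = sensitivities[key]
        grid = vol.grid
        values = vol.values if roi is None else vol.values[roi]
        roi_shape = tuple(np.asarray(values).shape)
        rows_W.append(np.asarray(values, float).ravel())
        if isinstance(calibration, dict):
            kappa = calibration[(round(link.sr_distance, 6), gate)]
        else:
            kappa = calibration
        rows_g.append(float(measurements[key]) * kappa)
        rows_meta.append(key)
    if not rows_W:
        raise AssemblyError("no rows assembled; check links and distances")
    W = np.vstack(rows_W)
    g = np.asarray(rows_g)
    if len(g) != entry.expected_links:
        meta_note = dict(expected_links=entry.expected_links,
                         actual_links=len(g))
    else:
        meta_note = {}
    return LinearSystem(W=W, g=g, grid=grid, rows=rows_meta,
                        meta=dict(velocity=entry.velocity,
                                  calibration=calibration,
                                  roi=roi is not None, roi_shape=roi_shape,
                                  **meta_note))


def calibrate_per_class(strategy: Strategy, links: list[SRLink],
                        sensitivities: dict, measurements: dict,
                        f_ref_fn, roi=None) -> dict:
    """Per-(SR distance, gate) calibration factors against a reference
    FPDF model.

    For every gate class used by the strategy, the factor κ minimizes
    ‖κ·m − W f_ref‖² over that class's rows, with f_ref the closed-form
    FPDF of the calibration phantom at the class's entry velocity
    (``f_ref_fn(velocity)`` must return that volume).  This is the
    synthetic analogue of anchoring each reconstruction's amplitude with
    calibration measurements on a known object: the early-photon
    asymptotic behind the linear model does not fix the absolute
    proportionality between a gated measurement and the sensitivity
    integral, and the residual factor depends on where the gate sits on
    the temporal response, hence one factor per (R, t) class.
    """
    factors: dict = {}
    for entry in strategy.entries:
        f_ref = np.asarray(f_ref_fn(entry.velocity), float)
        f_flat = (f_ref if roi is None else f_ref[roi]).ravel()
        for R in entry.used_sr_distances:
            gate = entry.gate_per_distance[R]
            num = 0.0
            den = 0.0
            for link in links:
                if abs(link.sr_distance - R) > 1e-9:
                    continue
                key = (link.key, gate)
                if key not in sensitivities or key not in measurements:
                    raise AssemblyError(f"missing data for {key}")
                vol = sensitivities[key].values
                w = (vol if roi is None else vol[roi]).ravel()
                m = float(measurements[key])
                num += m * float(w @ f_flat)
                den += m * m
            if den <= 0.0:
                raise AssemblyError(
                    f"cannot calibrate class (R={R}, t={gate}): no signal")
            factors[(round(R, 6), gate)] = num / den
    return factors


def calibrate_scalar(W: np.ndarray, g_raw: np.ndarray, f_ref: np.ndarray
                     ) -> float:
    """Global calibration scalar κ minimizing ‖κ·g_raw − W f_ref‖².

    Folds the unknown coupling/proportionality factor between gated
    measurements and the linear sensitivity model into one number, fixed
    once on a reference configuration and then applied to every assembled
    g.  κ does not affect ratios between reconstructions, so the separated
    lifetime is insensitive to it.
    """
    g_raw = np.asarray(g_raw, float)
    denom = float(g_raw @ g_raw)
    if denom <= 0.0:
        raise AssemblyError("cannot calibrate against all-zero measurements")
    return float(g_raw @ (W @ np.asarray(f_ref, float).ravel())) / denom
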