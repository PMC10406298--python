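"""Fitness landscapes over design parameters.

A fitness landscape tabulates the mean detection power and estimation
efficiency of freshly generated alternating sequences over a grid of
design parameters:

* ISI-bound landscapes sweep every (L_ISI, U_ISI) combination from 1 to
  20 s (cells with L > U masked), 100 sequences per cell by default.
* Partial-trial landscapes sweep the proportion of null targets (0 to
  0.5) against U_ISI (2 to 20 s) at a fixed L_ISI of 2 s.

Each replicate runs the full pipeline: sequence generation, profile
selection, graded neural input, second-order Volterra response, noise
at the configured SNR, and the prewhitened-GLM optimality measures.
Per-cell, per-replicate seeds are derived deterministically from the
master seed and the cell coordinates, so any subgrid or single cell can
be recomputed independently and bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .bold import HRFKernel, VolterraModel, canonical_hrf, volterra_response
from .design import DesignSpec, generate_alternating_sequence, insert_partial_trials
from .neural import build_neural_input, select_ttp_profile
from .noise import NoiseModel, combine_signal_noise, generate_noise
from .optimality import (
    DEFAULT_N_LAGS,
    OptimalityResult,
    build_detection_matrix,
    build_fir_matrix,
    detection_power,
    estimation_efficiency,
)

__all__ = [
    "FitnessLandscape",
    "evaluate_design",
    "run_simulation1",
    "run_simulation2",
    "export_landscape",
    "read_landscape",
    "plot_landscape",
]

logger = logging.getLogger(__name__)


@dataclass
class FitnessLandscape:
    """Mean optimality measures over a 2-D design-parameter grid.

    ``axis1`` indexes rows of the matrices (L_ISI values, or partial
    fractions), ``axis2`` the columns (U_ISI values).  Masked cells
    (invalid bounds or failed evaluation) hold NaN and are flagged in
    ``mask``.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    detection: np.ndarray
    efficiency: np.ndarray
    mask: np.ndarray
    n_reps: int
    seed: int
    axis_names: tuple[str, str] = ("l_isi", "u_isi")
    config: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (len(self.axis1), len(self.axis2))
        for name in ("detection", "efficiency", "mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} matrix does not match the grid shape")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def argmax(self, measure: str = "detection") -> tuple[float, float]:
        """Grid coordinates (axis1, axis2) of the maximal mean value."""
        m = getattr(self, measure)
        filled = np.where(self.mask, -np.inf, m)
        i, j = np.unravel_index(np.nanargmax(filled), filled.shape)
        return float(self.axis1[i]), float(self.axis2[j])


def _cell_rng(seed: int, a: float, b: float, rep: int) -> np.random.Generator:
    """Deterministic per-cell, per-replicate generator.

    The key mixes the master seed with the cell coordinates (scaled to
    integers) and the replicate index, so cells are independent and any
    subgrid reproduces the full run's values.
    """
    key = [int(seed), int(round(a * 1000)), int(round(b * 1000)), int(rep)]
    return np.random.default_rng(np.random.SeedSequence(key))


def evaluate_design(
    spec: DesignSpec,
    rng: np.random.Generator,
    hrf: HRFKernel | None = None,
    volterra: VolterraModel | None = None,
    noise_model: NoiseModel | None = None,
    enable_ttp: bool = True,
    scale_by_fit: bool = True,
    n_lags: int = DEFAULT_N_LAGS,
    noise_reference_sd: float = 1.0,
) -> OptimalityResult:
    """Run the full pipeline once and score the resulting design.

    Generates one sequence under ``spec`` (including partial trials if
    requested), builds its graded neural input, simulates the noisy
    order-2 BOLD series, and evaluates detection power (assumed-HRF
    GLM) and estimation efficiency (FIR GLM) on it.

    The noise level is fixed in absolute response units —
    sd(noise) = ``noise_reference_sd`` / snr, with 1.0 response unit
    being the peak of a unit isolated-event response — so every design
    on a landscape receives statistically identical noise, as if a
    single measured noise template were reused across simulations.
    """
    if hrf is None:
        hrf = canonical_hrf(dt=spec.tr)
    if volterra is None:
        volterra = VolterraModel()
    if noise_model is None:
        noise_model = NoiseModel()

    seq = generate_alternating_sequence(spec, rng)
    profile = select_ttp_profile(spec.l_isi, spec.u_isi, spec.paradigm, tr=spec.tr)
    u = build_neural_input(seq, profile, enable_ttp=enable_ttp)
    y = volterra_response(u, hrf, volterra)
    eta = generate_noise(noise_model, spec.n_scans, spec.tr, rng)
    data, _ = combine_signal_noise(
        y, eta, noise_model.snr, reference_sd=noise_reference_sd
    )

    det_setup = build_detection_matrix(seq, hrf)
    d = detection_power(det_setup, data, scale_by_fit=scale_by_fit)
    fir_setup = build_fir_matrix(seq, n_lags=n_lags)
    e = estimation_efficiency(fir_setup, data, scale_by_fit=scale_by_fit)
    return OptimalityResult(detection_power=d, estimation_efficiency=e)


def _mean_cell(
    spec: DesignSpec,
    seed: int,
    key_a: float,
    key_b: float,
    n_reps: int,
    **kwargs: Any,
) -> tuple[float, float]:
    d = np.empty(n_reps)
    e = np.empty(n_reps)
    for rep in range(n_reps):
        rng = _cell_rng(seed, key_a, key_b, rep)
        res = evaluate_design(spec, rng, **kwargs)
        d[rep] = res.detection_power
        e[rep] = res.estimation_efficiency
    return float(d.mean()), float(e.mean())


def run_simulation1(
    paradigm: str = "attention",
    isi_values: np.ndarray | None = None,
    n_reps: int = 100,
    seed: int = 0,
    tr: float = 1.5,
    n_scans: int = 294,
    noise_model: NoiseModel | None = None,
    volterra: VolterraModel | None = None,
    enable_ttp: bool = True,
    scale_by_fit: bool = True,
) -> FitnessLandscape:
    """ISI-bound fitness landscape for alternating cue–target designs.

    Sweeps every (L_ISI, U_ISI) pair over ``isi_values`` (default 1 to
    20 s, step 1) with L <= U, scoring each cell by the mean detection
    power and estimation efficiency of ``n_reps`` freshly jittered
    sequences.  Per-cell failures are masked and logged, never fatal.
    """
    if isi_values is None:
        isi_values = np.arange(1.0, 21.0)
    isi_values = np.asarray(isi_values, dtype=float)
    shape = (len(isi_values), len(isi_values))
    detection = np.full(shape, np.nan)
    efficiency = np.full(shape, np.nan)
    mask = np.ones(shape, dtype=bool)

    for i, l_isi in enumerate(isi_values):
        for j, u_isi in enumerate(isi_values):
            if l_isi > u_isi:
                continue
            spec = DesignSpec(
                l_isi=float(l_isi),
                u_isi=float(u_isi),
                tr=tr,
                n_scans=n_scans,
                paradigm=paradigm,
            )
            try:
                d, e = _mean_cell(
                    spec,
                    seed,
                    l_isi,
                    u_isi,
                    n_reps,
                    noise_model=noise_model,
                    volterra=volterra,
                    enable_ttp=enable_ttp,
                    scale_by_fit=scale_by_fit,
                )
            except Exception:
                logger.exception(
                    "cell (l_isi=%s, u_isi=%s) failed; masking", l_isi, u_isi
                )
                continue
            detection[i, j] = d
            efficiency[i, j] = e
            mask[i, j] = False
        logger.info("landscape row l_isi=%s done", l_isi)

    return FitnessLandscape(
        axis1=isi_values.copy(),
        axis2=isi_values.copy(),
        detection=detection,
        efficiency=efficiency,
        mask=mask,
        n_reps=n_reps,
        seed=seed,
        axis_names=("l_isi", "u_isi"),
        config={
            "paradigm": paradigm,
            "tr": tr,
            "n_scans": n_scans,
            "noise_model": (noise_model or NoiseModel()).__dict__ | {},
            "enable_ttp": enable_ttp,
            "scale_by_fit": scale_by_fit,
        },
    )


def run_simulation2(
    fractions: np.ndarray | None = None,
    u_isi_values: np.ndarray | None = None,
    l_isi: float = 2.0,
    n_reps: int = 100,
    seed: int = 0,
    tr: float = 1.5,
    n_scans: int = 294,
    noise_model: NoiseModel | None = None,
    volterra: VolterraModel | None = None,
    enable_ttp: bool = True,
    scale_by_fit: bool = True,
) -> FitnessLandscape:
    """Partial-trial fitness landscape (attention profiles only).

    Sweeps the proportion of null targets (default 0 to 0.5, step 0.1)
    against U_ISI (default 2 to 20 s, step 2) with L_ISI fixed.  Seeds
    depend on (L_ISI, U_ISI) but not the fraction, so the zero-fraction
    row reproduces the matching ISI-landscape cells exactly.
    """
    if fractions is None:
        fractions = np.arange(0.0, 0.51, 0.1)
    if u_isi_values is None:
        u_isi_values = np.arange(2.0, 21.0, 2.0)
    fractions = np.asarray(fractions, dtype=float)
    u_isi_values = np.asarray(u_isi_values, dtype=float)
    shape = (len(fractions), len(u_isi_values))
    detection = np.full(shape, np.nan)
    efficiency = np.full(shape, np.nan)
    mask = np.ones(shape, dtype=bool)

    for i, frac in enumerate(fractions):
        for j, u_isi in enumerate(u_isi_values):
            spec = DesignSpec(
                l_isi=l_isi,
                u_isi=float(u_isi),
                tr=tr,
                n_scans=n_scans,
                paradigm="attention",
                partial_fraction=float(frac),
            )
            try:
                d, e = _mean_cell(
                    spec,
                    seed,
                    l_isi,
                    u_isi,
                    n_reps,
                    noise_model=noise_model,
                    volterra=volterra,
                    enable_ttp=enable_ttp,
                    scale_by_fit=scale_by_fit,
                )
            except Exception:
                logger.exception(
                    "cell (fraction=%s, u_isi=%s) failed; masking", frac, u_isi
                )
                continue
            detection[i, j] = d
            efficiency[i, j] = e
            mask[i, j] = False
        logger.info("landscape row fraction=%s done", frac)

    return FitnessLandscape(
        axis1=fractions.copy(),
        axis2=u_isi_values.copy(),
        detection=detection,
        efficiency=efficiency,
        mask=mask,
        n_reps=n_reps,
        seed=seed,
        axis_names=("partial_fraction", "u_isi"),
        config={
            "paradigm": "attention",
            "l_isi": l_isi,
            "tr": tr,
            "n_scans": n_scans,
            "noise_model": (noise_model or NoiseModel()).__dict__ | {},
            "enable_ttp": enable_ttp,
            "scale_by_fit": scale_by_fit,
        },
    )


def export_landscape(ls: FitnessLandscape, path: str | Path) -> None:
    """Write a landscape as long-format CSV.

    One row per grid cell; masked cells carry ``masked = True`` with
    empty value fields.  Values are written at full float precision so
    :func:`read_landscape` round-trips losslessly.
    """
    rows = []
    for i, a in enumerate(ls.axis1):
        for j, b in enumerate(ls.axis2):
            masked = bool(ls.mask[i, j])
            rows.append(
                {
                    ls.axis_names[0]: a,
                    ls.axis_names[1]: b,
                    "detection": "" if masked else repr(float(ls.detection[i, j])),
                    "efficiency": "" if masked else repr(float(ls.efficiency[i, j])),
                    "n_reps": ls.n_reps,
                    "masked": masked,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landscape(path: str | Path) -> FitnessLandscape:
    """Reconstruct a landscape from its CSV export."""
    # value columns stay strings: Python's float() round-trips repr exactly,
    # the csv fast path may be off by an ulp
    df = pd.read_csv(path, dtype={"detection": str, "efficiency": str})
    axis_names = tuple(df.columns[:2])
    axis1 = np.unique(df[axis_names[0]].to_numpy(dtype=float))
    axis2 = np.unique(df[axis_names[1]].to_numpy(dtype=float))
    shape = (len(axis1), len(axis2))
    detection = np.full(shape, np.nan)
    efficiency = np.full(shape, np.nan)
    mask = np.ones(shape, dtype=bool)
    i_of = {v: i for i, v in enumerate(axis1)}
    j_of = {v: j for j, v in enumerate(axis2)}
    for _, row in df.iterrows():
        i = i_of[float(row[axis_names[0]])]
        j = j_of[float(row[axis_names[1]])]
        if not bool(row["masked"]):
            detection[i, j] = float(row["detection"])
            efficiency[i, j] = float(row["efficiency"])
            mask[i, j] = False
    return FitnessLandscape(
        axis1=axis1,
        axis2=axis2,
        detection=detection,
        efficiency=efficiency,
        mask=mask,
        n_reps=int(df["n_reps"].iloc[0]),
        seed=-1,
        axis_names=axis_names,  # type: ignore[arg-type]
    )


def plot_landscape(ls: FitnessLandscape, path: str | Path) -> None:
    """Render detection and efficiency heatmaps side by side to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), constrained_layout=True)
    for ax, measure, title in zip(
        axes, ("detection", "efficiency"), ("Detection power", "Estimation efficiency")
    ):
        m = np.ma.masked_where(ls.mask, getattr(ls, measure))
        im = ax.pcolormesh(ls.axis2, ls.axis1, m, shading="nearest", cmap="viridis")
        ax.set_xlabel(ls.axis_names[1])
        ax.set_ylabel(ls.axis_names[0])
        ax.set_title(title)
        fig.colorbar(im, ax=ax, label="arbitrary units")
    fig.savefig(path, dpi=150)
    plt.close(fig)
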