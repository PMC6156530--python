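"""Bifurcation diagrams over pacing rate, fork/eye classification, and the
synthetic myocyte population.

A bifurcation diagram records the last two beats' APD90, CaT amplitude and
JSR depletion fraction at each cycle length of a descending bcl sweep. In
*fork-type* alternans the APD split opens below some onset bcl and persists
at all faster rates; in *eye-type* alternans it closes again at the fastest
rates. Eye closure is mechanistically tied to functional JSR depletion in
both beats: once every release empties the JSR, the steep load-release
relationship is flattened and the oscillation cannot be sustained.

The population generator emulates a conductance-varied population-of-models
design by sampling independent log-normal multipliers for a handful of
calcium-handling parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import FULL_DEPLETION_THRESHOLD
from .model import ModelState
from .pacing import pace
from .params import ModelParameters

#: default APD-alternans significance threshold, ms (natural APD variability)
EPSILON_APD = 2.0

DEFAULT_BCL_GRID = tuple(np.arange(600.0, 249.0, -50.0))

#: parameters varied in the synthetic population
POPULATION_PARAMETERS = ("g_cal", "v_up", "tau_rel", "tau_tr", "gamma_ca")


@dataclass
class BifurcationDiagram:
    bcls: np.ndarray                 # descending, ms
    apd_pairs: np.ndarray            # (n, 2) last-two-beat APD90, ms
    cat_pairs: np.ndarray            # (n, 2) CaT amplitudes, mM
    depletion_pairs: np.ndarray      # (n, 2) depletion fractions
    quasi_stable: np.ndarray         # (n,) bool
    unstable: np.ndarray             # (n,) bool; non-repolarizing (2:1-like)
    params: Optional[ModelParameters] = None

    def d_apd(self) -> np.ndarray:
        return np.abs(self.apd_pairs[:, 0] - self.apd_pairs[:, 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bcl_ms": self.bcls,
            "apd1_ms": self.apd_pairs[:, 0], "apd2_ms": self.apd_pairs[:, 1],
            "cat1_mM": self.cat_pairs[:, 0], "cat2_mM": self.cat_pairs[:, 1],
            "depletion1": self.depletion_pairs[:, 0],
            "depletion2": self.depletion_pairs[:, 1],
            "quasi_stable": self.quasi_stable,
            "unstable": self.unstable,
        })


def bifurcation_diagram(params: ModelParameters,
                        bcls: Sequence[float] = DEFAULT_BCL_GRID, *,
                        beats_per_bcl: int = 1000, dt: float = 0.05,
                        warm_start: bool = True,
                        initial_state: Optional[ModelState] = None
                        ) -> BifurcationDiagram:
    """Pace the cell at each bcl of a descending sweep and record the final
    two beats.

    With ``warm_start`` each bcl continues from the previous (faster
    convergence of the slow variables); otherwise each bcl is paced
    independently from rest. A condition whose long APD reaches the cycle
    length (no full repolarization, akin to 2:1 block) is flagged unstable
    and terminates the sweep for this cell.
    """
    bcls = np.asarray(sorted(bcls, reverse=True), dtype=float)
    n = len(bcls)
    apd = np.full((n, 2), np.nan)
    cat = np.full((n, 2), np.nan)
    dep = np.full((n, 2), np.nan)
    qs = np.zeros(n, dtype=bool)
    unstable = np.zeros(n, dtype=bool)
    state = initial_state or ModelState()
    for i, bcl in enumerate(bcls):
        start = dataclasses.replace(state) if warm_start else ModelState()
        try:
            r = pace(start, params, bcl, beats_per_bcl, dt=dt)
        except Exception:
            unstable[i:] = True
            break
        b2 = r.beats.iloc[-2:]
        apd[i] = b2["apd90_ms"].to_numpy()
        cat[i] = b2["cat_amplitude_mM"].to_numpy()
        dep[i] = b2["depletion_fraction"].to_numpy()
        qs[i] = r.quasi_stable
        if not b2["repolarized"].all():
            unstable[i:] = True
            break
        if warm_start:
            state = r.end_state
    return BifurcationDiagram(bcls=bcls, apd_pairs=apd, cat_pairs=cat,
                              depletion_pairs=dep, quasi_stable=qs,
                              unstable=unstable, params=params)


def classify_alternans(diagram: BifurcationDiagram,
                       epsilon: float = EPSILON_APD) -> str:
    """Label the diagram ``none``, ``fork``, ``eye`` or ``unstable``.

    Scanning from slow to fast pacing (descending bcl), ``fork`` means the
    APD split exceeds ``epsilon`` from some bcl onward at every faster rate;
    ``eye`` means it exceeds and later falls back below ``epsilon``;
    unstable (non-repolarizing) bcls are excluded from the open/closed
    sequence.
    """
    valid = ~diagram.unstable & np.isfinite(diagram.d_apd())
    if not valid.any():
        return "unstable"
    d = diagram.d_apd()[valid]
    open_ = d >= epsilon
    if not open_.any():
        return "none"
    first = int(np.argmax(open_))
    if open_[first:].all():
        return "fork"
    return "eye"


@dataclass
class CooccurrenceResult:
    applicable: bool
    eye_closure_bcl: Optional[float] = None
    full_depletion_bcl: Optional[float] = None
    cooccur: bool = False


def depletion_cooccurrence(diagram: BifurcationDiagram,
                           epsilon: float = EPSILON_APD,
                           depletion_threshold: float =
                           FULL_DEPLETION_THRESHOLD) -> CooccurrenceResult:
    """For an eye-type diagram: does the bcl at which the alternans eye
    closes coincide with the first (largest) bcl at which both final beats
    reach full functional JSR depletion?"""
    if classify_alternans(diagram, epsilon) != "eye":
        return CooccurrenceResult(applicable=False)
    valid = ~diagram.unstable & np.isfinite(diagram.d_apd())
    bcls = diagram.bcls[valid]
    d = diagram.d_apd()[valid]
    dep_both = (diagram.depletion_pairs[valid] >= depletion_threshold).all(
        axis=1)
    first_open = int(np.argmax(d >= epsilon))
    closed = np.nonzero(d[first_open:] < epsilon)[0]
    eye_bcl = float(bcls[first_open + closed[0]])
    dep_bcl = float(bcls[np.argmax(dep_both)]) if dep_both.any() else None
    return CooccurrenceResult(applicable=True, eye_closure_bcl=eye_bcl,
                              full_depletion_bcl=dep_bcl,
                              cooccur=dep_bcl == eye_bcl)


# ---------------------------------------------------------------------------
# synthetic population

@dataclass
class PopulationSpec:
    """Log-normal conductance-multiplier population design."""

    n_cells: int = 200
    sigma: dict = field(default_factory=lambda: {
        name: 0.15 for name in POPULATION_PARAMETERS})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for k, s in self.sigma.items():
            if s < 0:
                raise ValueError(f"sigma for {k} must be >= 0")


def generate_population(spec: PopulationSpec,
                        base: Optional[ModelParameters] = None
                        ) -> tuple[list[ModelParameters], pd.DataFrame]:
    """Sample the population; deterministic given the spec's seed.

    Returns the per-cell parameter sets and a manifest of sampled
    multipliers (one row per cell).
    """
    base = base or ModelParameters.default()
    rng = np.random.default_rng(spec.seed)
    names = list(spec.sigma)
    mults = {n: np.exp(rng.normal(0.0, spec.sigma[n], spec.n_cells))
             for n in names}
    cells = []
    for i in range(spec.n_cells):
        cells.append(base.scaled(**{n: float(mults[n][i]) for n in names}))
    manifest = pd.DataFrame({"cell": np.arange(spec.n_cells)} |
                            {f"{n}_multiplier": mults[n] for n in names})
    return cells, manifest


def population_study(cells: Sequence[ModelParameters],
                     bcls: Sequence[float] = DEFAULT_BCL_GRID, *,
                     beats_per_bcl: int = 1000, dt: float = 0.05,
                     epsilon: float = EPSILON_APD,
                     warm_start: bool = True) -> dict:
    """Bifurcation + classification + depletion co-occurrence per cell.

    Returns per-cell labels and the aggregate counts, including the eye <->
    both-beat-full-depletion contingency. Per-cell failures are logged and
    excluded from the aggregates (count reported).
    """
    records = []
    diagrams = []
    failures = 0
    for i, p in enumerate(cells):
        try:
            diag = bifurcation_diagram(p, bcls, beats_per_bcl=beats_per_bcl,
                                       dt=dt, warm_start=warm_start)
            label = classify_alternans(diag, epsilon)
            co = depletion_cooccurrence(diag, epsilon)
            valid = ~diag.unstable & np.isfinite(diag.d_apd())
            dep_both_any = bool((diag.depletion_pairs[valid] >=
                                 FULL_DEPLETION_THRESHOLD).all(axis=1).any())
        except Exception:
            failures += 1
            continue
        records.append({
            "cell": i, "label": label,
            "cooccur": co.cooccur if co.applicable else None,
            "eye_closure_bcl": co.eye_closure_bcl,
            "full_depletion_bcl": co.full_depletion_bcl,
            "full_depletion_both_any": dep_both_any})
        diagrams.append(diag)
    frame = pd.DataFrame(records)
    counts = (frame["label"].value_counts().to_dict() if len(frame) else {})
    return {"cells": frame, "diagrams": diagrams, "counts": counts,
            "failures": failures}
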