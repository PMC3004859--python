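"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its arguments (including the seed):
identical calls give identical outputs.  The generators plant a known
truth — evidence-supported receptor→target paths in the interactome,
activated/suppressed TF sets on the arrays, peak fold changes in the
time courses, ODE parameters in the trajectories, a target correlation in
the image pairs — so that each consuming stage can be checked for exact
round-trip recovery at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactome import InteractionRecord
from .lyn_syk import OdeParameters, Trajectory, simulate
from .tf_array import TFArrayPlate

SOURCE_DATABASES = ("synthdb-A", "synthdb-B")
ARRAY_CONDITIONS = ("unstim", "20min", "40min")
DEFAULT_TIMEPOINTS = (0.0, 5.0, 10.0, 15.0, 30.0, 60.0)


@dataclass
class GroundTruth:
    """What a generator planted, for round-trip verification."""

    seed: int
    planted_paths: list[list[str]] = field(default_factory=list)
    planted_activated_tfs: set[str] = field(default_factory=set)
    planted_suppressed_tfs: set[str] = field(default_factory=set)
    planted_params: OdeParameters | None = None
    planted_rho: float | None = None
    interactome_nodes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.planted_activated_tfs & self.planted_suppressed_tfs:
            raise ValueError("activated and suppressed TF sets must be disjoint")
        if self.interactome_nodes:
            for path in self.planted_paths:
                for endpoint in (path[0], path[-1]):
                    if endpoint not in self.interactome_nodes:
                        raise ValueError(
                            f"planted path endpoint {endpoint!r} absent from interactome"
                        )


# ---------------------------------------------------------------------------
# interactome

def gen_interactome(
    n_nodes: int,
    n_edges: int,
    frac_multi_study: float = 0.5,
    planted_paths: list[list[str]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Multi-database interaction records with planted source→target paths.

    Every planted-path edge carries at least two distinct publications (so
    it survives the two-study filter) and appears in both synthetic source
    databases; of the remaining edges, a fraction ``frac_multi_study`` get
    multi-study support and the rest exactly one publication.  Publication
    IDs are shared across databases for overlapping edges, so the
    distinct-study filter is exercised both within and across sources.

    Returns a record table (columns id_a, id_b, publications, source_db)
    and the planted ground truth.
    """
    planted_paths = [list(p) for p in (planted_paths or [])]
    if not 0.0 <= frac_multi_study <= 1.0:
        raise ValueError("frac_multi_study must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    path_nodes: list[str] = []
    for path in planted_paths:
        for node in path:
            if node not in path_nodes:
                path_nodes.append(node)
    if len(path_nodes) > n_nodes:
        raise ValueError("planted paths reference more nodes than n_nodes")
    nodes = path_nodes + [f"P{i:04d}" for i in range(n_nodes - len(path_nodes))]

    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds maximum {max_edges} for {n_nodes} nodes")

    planted_edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for path in planted_paths:
        for u, v in zip(path, path[1:]):
            key = tuple(sorted((u, v)))
            if u == v:
                raise ValueError(f"planted path contains a self-loop at {u!r}")
            if key not in seen:
                seen.add(key)
                planted_edges.append(key)
    if len(planted_edges) > n_edges:
        raise ValueError("planted-path edges exceed n_edges")

    extra_edges: list[tuple[str, str]] = []
    while len(planted_edges) + len(extra_edges) < n_edges:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        key = tuple(sorted((nodes[i], nodes[j])))
        if key not in seen:
            seen.add(key)
            extra_edges.append(key)

    n_multi = round(frac_multi_study * len(extra_edges))
    multi_idx = set(rng.choice(len(extra_edges), size=n_multi, replace=False)) if extra_edges else set()

    pub_counter = 0

    def next_pubs(k: int) -> frozenset[str]:
        nonlocal pub_counter
        pubs = frozenset(f"PMID{pub_counter + i:06d}" for i in range(k))
        pub_counter += k
        return pubs

    records: list[InteractionRecord] = []
    for idx, (u, v) in enumerate(planted_edges + extra_edges):
        planted = idx < len(planted_edges)
        if planted:
            pubs = next_pubs(int(rng.integers(2, 6)))
            dbs = SOURCE_DATABASES  # planted edges overlap both databases
        else:
            pubs = next_pubs(int(rng.integers(2, 6)) if idx - len(planted_edges) in multi_idx else 1)
            dbs = (SOURCE_DATABASES[idx % 2],) if idx % 3 else SOURCE_DATABASES
        for db in dbs:
            records.append(InteractionRecord(u, v, pubs, db))

    frame = pd.DataFrame(
        [
            {
                "id_a": r.id_a,
                "id_b": r.id_b,
                "publications": "|".join(sorted(r.publications)),
                "source_db": r.source_db,
            }
            for r in records
        ],
        columns=["id_a", "id_b", "publications", "source_db"],
    )
    truth = GroundTruth(
        seed=seed, planted_paths=planted_paths, interactome_nodes=set(nodes)
    )
    return frame, truth


def records_from_frame(frame: pd.DataFrame) -> list[InteractionRecord]:
    return [
        InteractionRecord(
            row.id_a, row.id_b, frozenset(row.publications.split("|")), row.source_db
        )
        for row in frame.itertuples(index=False)
    ]


def write_mitab(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# TF arrays

def gen_tf_array(
    n_tfs: int = 345,
    n_border_controls: int = 16,
    activated: set[str] | None = None,
    suppressed: set[str] | None = None,
    fold_low: float = 4.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    tf_ids: list[str] | None = None,
) -> tuple[list[TFArrayPlate], GroundTruth]:
    """Duplicate array plates (2 replicates × unstim/20min/40min) with
    planted activations and repressions.

    Activated TFs exceed ``fold_low`` over basal at 40 min in both
    replicates (delayed kinetics); suppressed TFs fall below
    ``1/fold_low`` at both stimulated timepoints; all other TFs stay
    within [1/1.5, 1.5] of basal.  Explicit ``tf_ids`` (e.g. real TF
    symbols) may be supplied; planted sets must be drawn from them.
    """
    activated = set(activated or ())
    suppressed = set(suppressed or ())
    if activated & suppressed:
        raise ValueError("activated and suppressed TF sets overlap")
    if fold_low <= 2.0:
        raise ValueError("fold_low must exceed the 2-fold calling threshold")
    if n_border_controls < 1:
        raise ValueError("need at least one border control")
    if tf_ids is None:
        planted = sorted(activated) + sorted(suppressed)
        if len(planted) > n_tfs:
            raise ValueError("planted TF sets exceed n_tfs")
        fillers = []
        i = 0
        while len(planted) + len(fillers) < n_tfs:
            name = f"TF{i:04d}"
            if name not in activated and name not in suppressed:
                fillers.append(name)
            i += 1
        tf_ids = planted + fillers
    else:
        tf_ids = list(tf_ids)
        if len(tf_ids) != n_tfs:
            raise ValueError("tf_ids length must equal n_tfs")
        missing = (activated | suppressed) - set(tf_ids)
        if missing:
            raise ValueError(f"planted TFs absent from tf_ids: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    basal = {tf: rng.uniform(0.5, 2.0) for tf in tf_ids}

    # planted stimulated/basal ratios per (tf, condition, replicate)
    def ratio(tf: str, condition: str, replicate: int) -> float:
        if condition == "unstim":
            return 1.0
        if tf in activated:
            # delayed kinetics: activation shows only at 40 min
            return fold_low * rng.uniform(1.1, 1.5) if condition == "40min" else rng.uniform(0.9, 1.1)
        if tf in suppressed:
            return 1.0 / (fold_low * rng.uniform(1.1, 1.5))
        return rng.uniform(1.0 / 1.5, 1.5)

    plates = []
    for condition in ARRAY_CONDITIONS:
        for replicate in (1, 2):
            controls = [1000.0 * rng.uniform(0.8, 1.2) for _ in range(n_border_controls)]
            control_mean = float(np.mean(controls))
            spots = {}
            for tf in tf_ids:
                value = basal[tf] * ratio(tf, condition, replicate) * control_mean
                if noise_cv > 0:
                    value *= max(1.0 + noise_cv * rng.standard_normal(), 1e-6)
                spots[tf] = value
            plates.append(
                TFArrayPlate(
                    condition=condition,
                    replicate=replicate,
                    spots=spots,
                    border_controls=controls,
                )
            )
    truth = GroundTruth(
        seed=seed,
        planted_activated_tfs=activated,
        planted_suppressed_tfs=suppressed,
    )
    return plates, truth


# ---------------------------------------------------------------------------
# densitometry time courses

def gen_timecourse(
    targets: list[str],
    profiles: dict[str, tuple[float, float]],
    noise_cv: float = 0.0,
    seed: int = 0,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    curve_width: float = 10.0,
) -> pd.DataFrame:
    """Band-measurement table with planted peak fold changes.

    ``profiles`` maps each target to (peak_fold, peak_time_min).  The
    underlying fold curve is a Gaussian bump in log-fold space, anchored to
    exactly 1 at t=0 and exactly ``peak_fold`` at the peak time (so it
    never goes negative and the densitometry pipeline recovers the planted
    peak fold exactly at zero noise).  Each lane carries its own
    loading-control intensity and local backgrounds.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for target in targets:
        if target not in profiles:
            raise ValueError(f"no profile for target {target!r}")
        peak_fold, peak_time = profiles[target]
        if peak_fold <= 0:
            raise ValueError(f"peak fold must be positive for {target!r}")
        if not 0.0 <= peak_time <= 60.0:
            raise ValueError(f"peak time must lie in [0, 60] min for {target!r}")
        if peak_time == 0.0 and peak_fold != 1.0:
            raise ValueError(f"peak at t=0 contradicts the fold-1 baseline ({target!r})")
        grid = sorted(set(timepoints) | {0.0, peak_time})
        s0 = np.exp(-(peak_time**2) / (2 * curve_width**2))

        def fold_curve(t: float) -> float:
            if peak_fold == 1.0:
                return 1.0
            s = np.exp(-((t - peak_time) ** 2) / (2 * curve_width**2))
            # exponent 0 at t=0, 1 at the peak, floored so tails rest at fold 1
            exponent = max((s - s0) / (1.0 - s0), 0.0)
            return float(peak_fold**exponent)

        base = rng.uniform(0.5, 2.0)
        for t in grid:
            loading_corrected = 1000.0 * rng.uniform(0.7, 1.3)
            band_corrected = base * fold_curve(t) * loading_corrected
            if noise_cv > 0:
                band_corrected *= max(1.0 + noise_cv * rng.standard_normal(), 1e-6)
                loading_corrected *= max(1.0 + noise_cv * rng.standard_normal(), 1e-6)
            band_bg = 40.0 * rng.uniform(0.5, 1.5)
            loading_bg = 40.0 * rng.uniform(0.5, 1.5)
            rows.append(
                {
                    "target": target,
                    "timepoint_min": float(t),
                    "raw": band_corrected + band_bg,
                    "background": band_bg,
                    "loading_raw": loading_corrected + loading_bg,
                    "loading_background": loading_bg,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# image pairs

def gen_image_pair(
    shape: tuple[int, int] = (256, 256),
    rho: float = 0.6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two non-negative channels whose expected Pearson coefficient is ``rho``.

    The second channel mixes the first with an independent Gaussian field
    (``rho*Z + sqrt(1-rho^2)*X``); each channel is then shifted — never
    clipped — to non-negative values, which leaves the sample correlation
    unchanged.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    if shape[0] < 16 or shape[1] < 16:
        raise ValueError("shape must be at least (16, 16)")
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(shape)
    independent = rng.standard_normal(shape)
    ch1 = shared
    ch2 = rho * shared + np.sqrt(max(1.0 - rho * rho, 0.0)) * independent
    ch1 = ch1 - min(ch1.min(), 0.0)
    ch2 = ch2 - min(ch2.min(), 0.0)
    return ch1, ch2


# ---------------------------------------------------------------------------
# TF->gene candidate table (synthetic stand-in)

def synthetic_candidate_table() -> pd.DataFrame:
    """Synthetic stand-in for the study's TF→gene candidate table.

    The TF symbols (sixteen candidates, of which seven were array-modulated)
    and the eleven early-induced gene symbols are as published; the
    individual gene→TF edge assignments and provenance labels are synthetic,
    constructed so that every gene has at least one candidate regulator and
    every candidate TF at least one target gene.
    """
    from .study_inputs import (
        CANDIDATE_TFS,
        EARLY_INDUCED_GENES,
        MODULATED_CANDIDATE_TFS,
    )

    genes = sorted(EARLY_INDUCED_GENES)
    tfs = sorted(CANDIDATE_TFS)
    rows = []
    # deterministic round-robin: gene i linked to 3 TFs starting at offset i
    for i, gene in enumerate(genes):
        for j in range(3):
            tf = tfs[(i + j * 5) % len(tfs)]
            provenance = "scan" if (i + j) % 2 == 0 else "literature"
            rows.append({"gene": gene, "tf": tf, "provenance": provenance})
    covered = {r["tf"] for r in rows}
    for k, tf in enumerate(t for t in tfs if t not in covered):
        rows.append({"gene": genes[k % len(genes)], "tf": tf, "provenance": "scan"})
    frame = pd.DataFrame(rows).drop_duplicates(["gene", "tf", "provenance"])
    assert MODULATED_CANDIDATE_TFS <= set(frame.tf)
    return frame.sort_values(["gene", "tf"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# ODE trajectories

def gen_trajectory(
    params: OdeParameters,
    t_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Deterministic model solution plus i.i.d. Gaussian noise, floored at 0."""
    t_grid = np.asarray(t_grid, dtype=float)
    steps = np.diff(t_grid)
    if len(t_grid) < 2 or not np.allclose(steps, steps[0]):
        raise ValueError("t_grid must be uniform with at least two points")
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    traj = simulate(params, t_end=float(t_grid[-1]), dt_out=float(steps[0]))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = np.vstack([traj.Lp, traj.Sm, traj.Sp])
        noisy = np.clip(noisy + noise_sd * rng.standard_normal(noisy.shape), 0.0, None)
        return Trajectory(t=traj.t, Lp=noisy[0], Sm=noisy[1], Sp=noisy[2])
    return traj
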