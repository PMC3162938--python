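"""Synthetic two-condition expression studies with known ground truth.

The generator emulates the data situation of a light-shift acclimation
experiment: a handful of transcription factors drive a few dozen target
genes through the same stochastic dynamic regulation model that the
inference stage assumes,

    dy/dt = sum_i b_i * x_i(t) - beta * y(t) + k,      x_i = sigmoid(TF_i),

sampled on the sparse non-uniform design grid {0, 0.5, 2, 8, 48} h with
three replicates per time point and Gaussian measurement noise.  Each
condition gets its own TF trajectories and its own planted regulator sets
(including, optionally, a condition-specific hub TF), while the candidate
prediction table — standing in for sequence-based promoter-binding
predictions — is condition-independent and salted with decoy edges.  Truth
labels (regulator sets, kinetic parameters) are kept in a sidecar record
and never written into pipeline-facing inputs.

Every output is a pure function of the arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .dataset import ExpressionDataset, TimeSeriesExpression, normalize_gene_id
from .errors import CapacityError, GridError, MissingProfileError
from .rough import CandidateEdge

__all__ = [
    "GroundTruth",
    "SyntheticStudy",
    "DESIGN_TIMES",
    "generate_tf_profiles",
    "simulate_target_gene",
    "downsample_to_design",
    "generate_candidate_table",
    "generate_study",
]

#: measurement design: sample before the shift and at 0.5, 2, 8, 48 h after
DESIGN_TIMES = (0.0, 0.5, 2.0, 8.0, 48.0)

#: default replicate count (independent hybridisations per time point)
N_REPLICATES = 3

#: default dense simulation grid spacing (hours); generation fidelity must
#: exceed the inference-side discretisation so recovery tests probe the
#: inference, not the simulator
DENSE_STEP = 0.1


@dataclass
class GroundTruth:
    """Planted truth for one condition's regulatory system.

    Maps every target to its regulator set and the kinetic parameters of
    its dynamic model: per-edge regulatory abilities ``b`` (expression
    units/h per unit sigmoid activity), degradation rate ``beta`` (1/h,
    positive), basal production ``k`` (units/h), optional initial level
    ``y0`` (steady state at t=0 when absent), plus the shared sigmoid
    calibration (transition rate ``r``, per-TF location ``m`` and scale
    ``s``) and the measurement noise sd per gene.
    """

    condition: str
    regulators: dict[str, tuple[str, ...]]
    b: dict[str, dict[str, float]]
    beta: dict[str, float]
    k: dict[str, float]
    sigma_eps: float
    r: float
    tf_means: dict[str, float]
    tf_scales: dict[str, float]
    seed: int
    y0: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for target, beta in self.beta.items():
            if beta <= 0:
                raise ValueError(f"target {target!r}: degradation rate must be positive")
        for target, regs in self.regulators.items():
            for tf in regs:
                if tf not in self.tf_means:
                    raise ValueError(
                        f"regulator {tf!r} of {target!r} has no sigmoid calibration"
                    )

    def edge_set(self) -> set[tuple[str, str]]:
        return {(tf, t) for t, regs in self.regulators.items() for tf in regs}

    def to_json(self) -> dict:
        payload = asdict(self)
        payload["regulators"] = {t: list(r) for t, r in self.regulators.items()}
        return payload


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise GridError("time grid must be 1-D and strictly increasing")
    return grid


def generate_tf_profiles(
    n_tf: int, dense_grid, seed: int, prefix: str = "TF"
) -> dict[str, TimeSeriesExpression]:
    """Smooth, bounded driver trajectories standing in for measured TF mRNA.

    Shift-response transcript kinetics come in qualitatively different
    shapes — saturating induction or repression, a transient pulse that
    relaxes back, and a delayed switch — and a benchmark in which every TF
    followed the same shape would make regulator identity unidentifiable
    (any candidate could substitute for any other).  Profiles therefore
    cycle through these three archetypes with randomised time constants,
    onsets and amplitudes, plus a slow sinusoidal drift; every component is
    a smooth low-frequency signal that the sparse design grid can resolve.
    Deterministic given ``(n_tf, dense_grid, seed)``.
    """
    if n_tf < 0:
        raise ValueError("n_tf must be non-negative")
    grid = _check_grid(dense_grid) if n_tf else np.asarray(dense_grid, dtype=float)
    rng = np.random.default_rng(seed)
    profiles: dict[str, TimeSeriesExpression] = {}
    for i in range(n_tf):
        base = rng.uniform(2.0, 4.0)
        amp = rng.uniform(0.8, 2.0) * rng.choice([-1.0, 1.0])
        kind = i % 3
        if kind == 0:  # saturating relaxation to a new level
            tau = rng.uniform(1.5, 8.0)
            shape = 1.0 - np.exp(-grid / tau)
        elif kind == 1:  # early transient pulse peaking at tau, relaxing back
            tau = rng.uniform(1.0, 4.0)
            shape = (grid / tau) * np.exp(1.0 - grid / tau)
        else:  # delayed sigmoidal switch
            onset = rng.uniform(0.5, 6.0)
            width = rng.uniform(0.5, 3.0)
            shape = 1.0 / (1.0 + np.exp(-(grid - onset) / width))
        drift = rng.uniform(0.1, 0.3) * np.sin(
            2 * np.pi * grid / rng.uniform(96.0, 192.0) + rng.uniform(0.0, 2 * np.pi)
        )
        values = base + amp * shape + drift
        name = f"{prefix}{i + 1:03d}"
        profiles[name] = TimeSeriesExpression(name, grid, values[:, None])
    return profiles


def _tf_spline(profile: TimeSeriesExpression) -> CubicSpline:
    return CubicSpline(profile.times, profile.mean_profile())


def _sigmoid(z, r, m, s):
    return 1.0 / (1.0 + np.exp(-r * (np.asarray(z) - m) / s))


def simulate_target_gene(
    truth: GroundTruth,
    target: str,
    tf_profiles: Mapping[str, TimeSeriesExpression],
    dense_grid,
    rng: np.random.Generator | None = None,
) -> TimeSeriesExpression:
    """Forward-integrate one target's dynamic model on the dense grid.

    Classical fixed-step 4th-order Runge-Kutta on ``dense_grid`` (assumed
    uniform); the regulatory inputs x_i(t) are sigmoids of the TF
    trajectories (evaluated through a cubic spline so RK4 midpoints are
    available).  Gaussian noise of sd ``truth.sigma_eps`` is added i.i.d.
    at each output point.  The initial level defaults to the t=0 steady
    state of the noise-free model.
    """
    target = normalize_gene_id(target)
    grid = _check_grid(dense_grid)
    regs = truth.regulators.get(target, ())
    for tf in regs:
        if tf not in tf_profiles:
            raise MissingProfileError(f"regulator {tf!r} of {target!r} has no profile")
    splines = {tf: _tf_spline(tf_profiles[tf]) for tf in regs}
    b = truth.b.get(target, {})
    beta = truth.beta[target]
    k = truth.k[target]
    r = truth.r

    def drive(t: float) -> float:
        total = 0.0
        for tf in regs:
            x = _sigmoid(splines[tf](t), r, truth.tf_means[tf], truth.tf_scales[tf])
            total += b[tf] * float(x)
        return total

    def rhs(t: float, y: float) -> float:
        return drive(t) - beta * y + k

    y0 = truth.y0.get(target)
    if y0 is None:
        y0 = (drive(grid[0]) + k) / beta
    y = np.empty_like(grid)
    y[0] = y0
    for j in range(grid.size - 1):
        t, h = grid[j], grid[j + 1] - grid[j]
        k1 = rhs(t, y[j])
        k2 = rhs(t + h / 2, y[j] + h * k1 / 2)
        k3 = rhs(t + h / 2, y[j] + h * k2 / 2)
        k4 = rhs(t + h, y[j] + h * k3)
        y[j + 1] = y[j] + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6
    if truth.sigma_eps > 0:
        if rng is None:
            rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.sigma_eps, size=y.shape)
    return TimeSeriesExpression(target, grid, y[:, None])


def downsample_to_design(
    profile: TimeSeriesExpression,
    design_times: Sequence[float] = DESIGN_TIMES,
    n_reps: int = N_REPLICATES,
    rep_noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeSeriesExpression:
    """Sample a dense trajectory at the design times with replicate noise.

    Each of the ``n_reps`` replicates at a time point is an independent
    Gaussian draw around the trajectory value (sd ``rep_noise_sd``),
    emulating independent hybridisation experiments.
    """
    design = np.asarray(design_times, dtype=float)
    times = profile.times
    if design.min() < times[0] or design.max() > times[-1]:
        raise GridError(
            f"design times must lie within the simulated span "
            f"[{times[0]}, {times[-1]}]"
        )
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    base = np.interp(design, times, profile.mean_profile())
    rng = np.random.default_rng(seed)
    values = np.repeat(base[:, None], n_reps, axis=1)
    if rep_noise_sd > 0:
        values = values + rng.normal(0.0, rep_noise_sd, size=values.shape)
    return TimeSeriesExpression(profile.gene, design, values)


def generate_candidate_table(
    truth: GroundTruth,
    decoys_per_target: int,
    tf_pool: Sequence[str],
    seed: int,
) -> list[CandidateEdge]:
    """True edges plus decoy TF->target predictions.

    Emulates a promoter-scan prediction table: predicted binding does not
    imply regulation, so each target receives ``decoys_per_target`` extra
    candidate regulators drawn (without replacement) from ``tf_pool``
    excluding its true regulators.  Truth labels are not carried on the
    emitted rows.
    """
    if decoys_per_target < 0:
        raise ValueError("decoys_per_target must be non-negative")
    pool = [normalize_gene_id(t) for t in tf_pool]
    rng = np.random.default_rng(seed)
    edges: list[CandidateEdge] = []
    seen: set[tuple[str, str]] = set()
    for target in sorted(truth.regulators):
        regs = truth.regulators[target]
        for tf in regs:
            if (tf, target) not in seen:
                seen.add((tf, target))
                edges.append(CandidateEdge(tf, target))
        available = [t for t in pool if t not in regs and t != target]
        if decoys_per_target > len(available):
            raise CapacityError(
                f"target {target!r}: requested {decoys_per_target} decoys but only "
                f"{len(available)} non-regulator TFs are available"
            )
        decoys = rng.choice(available, size=decoys_per_target, replace=False)
        for tf in sorted(decoys):
            if (tf, target) not in seen:
                seen.add((tf, target))
                edges.append(CandidateEdge(tf, target))
    return edges


# ---------------------------------------------------------------------------
# full study generation


@dataclass
class SyntheticStudy:
    """A complete two-condition synthetic study.

    ``datasets`` maps condition labels to design-sampled expression data
    (targets and TFs together), ``candidates`` is the condition-independent
    prediction table, ``seed_genes`` the Stage I seed list, and ``truths``
    the per-condition ground truth (sidecar material, not a pipeline
    input).
    """

    datasets: dict[str, ExpressionDataset]
    candidates: list[CandidateEdge]
    seed_genes: list[str]
    truths: dict[str, GroundTruth]
    seed: int

    def write(self, out_dir) -> dict[str, Path]:
        """Write the pipeline input files plus the ground-truth sidecar."""
        from . import io as _io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for label, ds in self.datasets.items():
            p = out / f"expression_{label}.tsv"
            _io.write_expression_matrix(ds, p)
            paths[f"expression_{label}"] = p
        paths["candidates"] = _io.write_candidate_table(self.candidates, out / "candidates.tsv")
        paths["seed_genes"] = _io.write_gene_list(self.seed_genes, out / "seed_genes.txt")
        sidecar = {
            "seed": self.seed,
            "truths": {label: t.to_json() for label, t in self.truths.items()},
        }
        p = out / "ground_truth.json"
        p.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        paths["ground_truth"] = p
        return paths


def _draw_truth(
    condition: str,
    targets: Sequence[str],
    tf_profiles: Mapping[str, TimeSeriesExpression],
    rng: np.random.Generator,
    *,
    r: float,
    regs_per_target: tuple[int, int],
    hub: str | None,
    hub_fraction: float,
    seed: int,
) -> GroundTruth:
    tf_ids = sorted(tf_profiles)
    tf_means = {tf: float(tf_profiles[tf].mean_profile().mean()) for tf in tf_ids}
    tf_scales = {}
    for tf in tf_ids:
        sd = float(tf_profiles[tf].mean_profile().std())
        tf_scales[tf] = sd if sd > 0 else 1.0
    regulators: dict[str, tuple[str, ...]] = {}
    b: dict[str, dict[str, float]] = {}
    beta: dict[str, float] = {}
    k: dict[str, float] = {}
    lo, hi = regs_per_target
    for target in targets:
        n_regs = int(rng.integers(lo, hi + 1))
        chosen: list[str] = []
        if hub is not None and rng.random() < hub_fraction:
            chosen.append(hub)
        others = [t for t in tf_ids if t not in chosen]
        extra = rng.choice(others, size=max(0, n_regs - len(chosen)), replace=False)
        chosen.extend(sorted(extra))
        regulators[target] = tuple(sorted(chosen))
        b[target] = {
            tf: float(rng.uniform(0.8, 2.0) * rng.choice([-1.0, 1.0]))
            for tf in regulators[target]
        }
        beta[target] = float(rng.uniform(0.2, 0.6))
        # basal rate large enough that production stays positive even when
        # every repressor saturates, so expression stays in positive units
        k[target] = float(rng.uniform(0.5, 1.5)) - sum(
            min(v, 0.0) for v in b[target].values()
        )
    return GroundTruth(
        condition=condition,
        regulators=regulators,
        b=b,
        beta=beta,
        k=k,
        sigma_eps=0.0,
        r=r,
        tf_means=tf_means,
        tf_scales=tf_scales,
        seed=seed,
    )


def generate_study(
    seed: int,
    *,
    n_targets: int = 58,
    n_tf: int = 7,
    conditions: Sequence[str] = ("PSI-to-PSII", "PSII-to-PSI"),
    design_times: Sequence[float] = DESIGN_TIMES,
    n_reps: int = N_REPLICATES,
    noise_frac: float = 0.05,
    regs_per_target: tuple[int, int] = (1, 3),
    decoys_per_target: int = 4,
    plant_hubs: bool = True,
    hub_fraction: float = 0.6,
    r: float = 1.0,
    dense_step: float = DENSE_STEP,
) -> SyntheticStudy:
    """Generate a full two-condition study at the reference design.

    Defaults mirror the experiment the pipeline targets: 58 targets plus 7
    TFs (65 measured genes), two light-shift conditions sampled at
    {0, 0.5, 2, 8, 48} h with 3 replicates, and replicate noise with sd
    equal to ``noise_frac`` (5%) of each gene's temporal signal sd.  Each
    condition plants one hub TF (TF001 for the first condition, TF002 for
    the second) that regulates ``hub_fraction`` of the targets, giving the
    differential comparison a known answer.
    """
    design = np.asarray(design_times, dtype=float)
    dense_grid = np.arange(design[0], design[-1] + dense_step / 2, dense_step)
    root = np.random.SeedSequence(seed)
    cond_seeds = root.spawn(len(conditions))
    targets = [f"G{i + 1:03d}" for i in range(n_targets)]
    datasets: dict[str, ExpressionDataset] = {}
    truths: dict[str, GroundTruth] = {}
    for ci, (label, ss) in enumerate(zip(conditions, cond_seeds)):
        child = np.random.default_rng(ss)
        tf_seed = int(ss.generate_state(1)[0] % (2**31))
        tf_profiles = generate_tf_profiles(n_tf, dense_grid, tf_seed)
        hub = sorted(tf_profiles)[ci % max(n_tf, 1)] if (plant_hubs and n_tf) else None
        truth = _draw_truth(
            label, targets, tf_profiles, child,
            r=r, regs_per_target=regs_per_target,
            hub=hub, hub_fraction=hub_fraction, seed=tf_seed,
        )
        profiles = []
        for target in targets:
            dense = simulate_target_gene(truth, target, tf_profiles, dense_grid)
            signal_sd = float(
                np.interp(design, dense_grid, dense.mean_profile()).std()
            )
            rep_seed = int(child.integers(0, 2**31))
            profiles.append(
                downsample_to_design(
                    dense, design, n_reps,
                    rep_noise_sd=noise_frac * signal_sd, seed=rep_seed,
                )
            )
        for tf in sorted(tf_profiles):
            dense = tf_profiles[tf]
            signal_sd = float(
                np.interp(design, dense_grid, dense.mean_profile()).std()
            )
            rep_seed = int(child.integers(0, 2**31))
            profiles.append(
                downsample_to_design(
                    dense, design, n_reps,
                    rep_noise_sd=noise_frac * signal_sd, seed=rep_seed,
                )
            )
        datasets[label] = ExpressionDataset(label, profiles)
        truths[label] = truth
    # condition-independent prediction table: union of the conditions' true
    # edges plus decoys, as sequence-based binding predictions would be
    tf_pool = [f"TF{i + 1:03d}" for i in range(n_tf)]
    table_seed = int(root.generate_state(1)[0] % (2**31))
    seen: set[tuple[str, str]] = set()
    candidates: list[CandidateEdge] = []
    for label in conditions:
        for edge in generate_candidate_table(
            truths[label], decoys_per_target, tf_pool, table_seed
        ):
            if edge.pair not in seen:
                seen.add(edge.pair)
                candidates.append(edge)
    return SyntheticStudy(
        datasets=datasets,
        candidates=candidates,
        seed_genes=list(targets),
        truths=truths,
        seed=seed,
    )
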