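"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* :func:`simulate_treatment_experiment` — an 8-arm drug-treatment design
  (vehicle; entinostat E, all-trans retinoic acid A, doxorubicin D; and their
  combinations EA, ED, AD, EAD) with replicates spread across batches and
  planted per-module log2 effects: interferon genes up in the ED/EAD arms,
  cell-cycle (MYC/E2F/G2M-style) genes down, entinostat effects predominantly
  upward.
* :func:`simulate_cohort` — a tumor cohort with a continuous latent
  immune-infiltration gradient drawn from a 3-component location mixture,
  loading on a core immune gene module and (more weakly) on an interferon
  module.
* :func:`simulate_survival` — exponential event times whose hazard depends
  log-linearly on a per-sample score, with independent and administrative
  right-censoring.

All randomness flows through a single integer seed; identical (config, seed)
gives bit-identical output.  Each generator returns its ground truth (planted
effects, latent infiltration and group, true hazard model) so downstream
recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import ExpressionMatrix, SampleAnnotation, SurvivalTable

__all__ = [
    "TreatmentDesign",
    "EffectModel",
    "CohortModel",
    "SurvivalModel",
    "default_design",
    "default_effect_model",
    "null_effect_model",
    "planted_synergy_model",
    "simulate_treatment_experiment",
    "simulate_cohort",
    "simulate_survival",
]

ARMS = ("Veh", "E", "A", "D", "EA", "ED", "AD", "EAD")


@dataclass
class TreatmentDesign:
    """Arms × replicates layout with replicates assigned round-robin to batches.

    Replicate ``r`` (1-based) of every arm goes to batch ``batches[(r-1) %
    len(batches)]``, so every arm appears in every batch whenever
    ``replicates_per_arm >= len(batches)``.
    """

    arms: tuple[str, ...] = ARMS
    replicates_per_arm: int = 4
    batches: tuple[str, ...] = ("b1", "b2")

    def __post_init__(self) -> None:
        if len(set(self.arms)) != len(self.arms):
            raise ValueError("arm labels must be unique")
        if "Veh" not in self.arms:
            raise ValueError('design must include a "Veh" (vehicle) arm')
        if self.replicates_per_arm < 1:
            raise ValueError("replicates_per_arm must be positive")
        if not self.batches:
            raise ValueError("at least one batch required")

    def layout(self) -> pd.DataFrame:
        rows = []
        for arm in self.arms:
            for rep in range(1, self.replicates_per_arm + 1):
                batch = self.batches[(rep - 1) % len(self.batches)]
                rows.append(
                    {"sample_id": f"{arm}_r{rep}", "arm": arm, "batch": batch, "replicate": rep}
                )
        return pd.DataFrame(rows)

    @property
    def n_samples(self) -> int:
        return len(self.arms) * self.replicates_per_arm


@dataclass
class EffectModel:
    """Planted per-(arm, module) log2 effects on a fixed gene universe.

    ``modules`` maps module names (e.g. ``ifn``, ``cell_cycle``, ``arrest``)
    to disjoint gene index arrays; ``module_effects[arm][module]`` is a signed
    log2 shift applied to every gene of that module under that arm.  On top of
    the module structure each arm may carry an arm-specific background
    signature: ``signature_sizes[arm]`` background genes at magnitude
    ``signature_effects[arm]``, split up/down by ``fraction_up[arm]``
    (directionality mix; the entinostat default is 0.96, mirroring the
    strongly upward skew HDAC inhibition produces).  Signature genes are
    allocated deterministically from the background pool in arm order, so the
    model itself involves no randomness.
    """

    n_genes: int
    modules: dict[str, np.ndarray]
    module_effects: dict[str, dict[str, float]]
    fraction_up: dict[str, float] = field(default_factory=dict)
    signature_sizes: dict[str, int] = field(default_factory=dict)
    signature_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.3
    baseline: np.ndarray | None = None
    batch_shifts: dict[str, np.ndarray] | None = None
    batch_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        all_idx = np.concatenate([np.asarray(v, dtype=int) for v in self.modules.values()]) \
            if self.modules else np.array([], dtype=int)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("gene modules must be disjoint")
        if all_idx.size and (all_idx.min() < 0 or all_idx.max() >= self.n_genes):
            raise ValueError("module gene index out of range")
        for arm, frac in self.fraction_up.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction_up for arm {arm!r} must be in [0, 1]")
        for arm, per_mod in self.module_effects.items():
            if arm == "Veh" and any(v != 0 for v in per_mod.values()):
                raise ValueError('effects for arm "Veh" must all be zero')
            for mod in per_mod:
                if mod not in self.modules:
                    raise ValueError(f"effect references unknown module {mod!r}")
        if self.baseline is not None and len(self.baseline) != self.n_genes:
            raise ValueError("baseline length must equal n_genes")

    def referenced_arms(self) -> set[str]:
        return set(self.module_effects) | set(self.signature_sizes)

    def effect_table(self, arms: tuple[str, ...]) -> pd.DataFrame:
        """Per-gene per-arm signed log2 effect (the ground truth)."""
        genes = [f"G{i:05d}" for i in range(self.n_genes)]
        table = pd.DataFrame(0.0, index=genes, columns=list(arms))
        for arm, per_mod in self.module_effects.items():
            for mod, eff in per_mod.items():
                table.iloc[self.modules[mod], table.columns.get_loc(arm)] = eff
        # background signature genes: allocated sequentially from the unused pool
        in_module = np.zeros(self.n_genes, dtype=bool)
        for idx in self.modules.values():
            in_module[np.asarray(idx, dtype=int)] = True
        pool = np.flatnonzero(~in_module)
        cursor = 0
        for arm in arms:
            n = self.signature_sizes.get(arm, 0)
            if n == 0:
                continue
            if cursor + n > pool.size:
                raise ValueError("background pool exhausted by signature allocations")
            chosen = pool[cursor : cursor + n]
            cursor += n
            frac = self.fraction_up.get(arm, 0.5)
            n_up = int(round(frac * n))
            mag = self.signature_effects.get(arm, 1.0)
            col = table.columns.get_loc(arm)
            table.iloc[chosen[:n_up], col] = mag
            table.iloc[chosen[n_up:], col] = -mag
        return table


def default_design(replicates_per_arm: int = 4) -> TreatmentDesign:
    return TreatmentDesign(replicates_per_arm=replicates_per_arm)


def _default_modules(n_genes: int) -> dict[str, np.ndarray]:
    if n_genes < 400:
        raise ValueError("default modules need at least 400 genes")
    return {
        "ifn": np.arange(0, 60),
        "cell_cycle": np.arange(60, 180),
        "arrest": np.arange(180, 230),
    }


def default_effect_model(n_genes: int = 2000, noise_sd: float = 0.3, seed: int = 0) -> EffectModel:
    """Study-condition defaults: ED/EAD drive interferon genes up and
    cell-cycle genes down; entinostat effects are predominantly upward;
    the A arm barely differs from vehicle."""
    rng = np.random.default_rng(seed)
    design = default_design()
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    shifts = {b: rng.normal(0.0, 0.3, size=n_genes) for b in design.batches}
    return EffectModel(
        n_genes=n_genes,
        modules=_default_modules(n_genes),
        module_effects={
            "E": {"arrest": 1.0},
            "A": {},
            "D": {"cell_cycle": -1.0},
            "EA": {"arrest": 1.0},
            "ED": {"ifn": 1.8, "cell_cycle": -1.5, "arrest": 1.5},
            "AD": {"cell_cycle": -1.0},
            "EAD": {"ifn": 1.8, "cell_cycle": -1.5, "arrest": 1.5},
        },
        fraction_up={"E": 0.96, "A": 0.5, "D": 0.5, "EA": 0.9, "ED": 0.7, "AD": 0.5, "EAD": 0.7},
        signature_sizes={"E": 190, "A": 10, "D": 100, "EA": 150, "ED": 400, "AD": 120, "EAD": 380},
        signature_effects={"E": 1.2, "A": 1.0, "D": 1.0, "EA": 1.0, "ED": 1.2, "AD": 1.0, "EAD": 1.2},
        noise_sd=noise_sd,
        baseline=baseline,
        batch_shifts=shifts,
    )


def null_effect_model(n_genes: int = 2000, noise_sd: float = 0.3, seed: int = 0) -> EffectModel:
    """All planted effects zero — the global null for calibration checks."""
    rng = np.random.default_rng(seed)
    design = default_design()
    return EffectModel(
        n_genes=n_genes,
        modules={},
        module_effects={},
        noise_sd=noise_sd,
        baseline=rng.normal(8.0, 1.0, size=n_genes),
        batch_shifts={b: rng.normal(0.0, 0.3, size=n_genes) for b in design.batches},
    )


def planted_synergy_model(
    n_genes: int = 2000,
    n_synergy: int = 100,
    n_single: int = 200,
    effect: float = 1.5,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> EffectModel:
    """Effect model for synergy-recovery checks.

    ``synergy`` genes respond only in the ED arm (half up, half down at
    ``±effect``); ``e_only``/``d_only`` genes respond identically in the
    single-agent arm and every combination containing it, so their
    combination-vs-single fold change is zero and a correct synergy call must
    exclude them.
    """
    rng = np.random.default_rng(seed)
    half = n_single // 2
    modules = {
        "synergy_up": np.arange(0, n_synergy // 2),
        "synergy_down": np.arange(n_synergy // 2, n_synergy),
        "e_only": np.arange(n_synergy, n_synergy + half),
        "d_only": np.arange(n_synergy + half, n_synergy + 2 * half),
    }
    e_arms = ("E", "EA", "ED", "EAD")
    d_arms = ("D", "AD", "ED", "EAD")
    module_effects: dict[str, dict[str, float]] = {arm: {} for arm in ARMS if arm != "Veh"}
    for arm in e_arms:
        module_effects[arm]["e_only"] = effect
    for arm in d_arms:
        module_effects[arm]["d_only"] = effect
    module_effects["ED"]["synergy_up"] = effect
    module_effects["ED"]["synergy_down"] = -effect
    design = default_design()
    return EffectModel(
        n_genes=n_genes,
        modules=modules,
        module_effects=module_effects,
        noise_sd=noise_sd,
        baseline=rng.normal(8.0, 1.0, size=n_genes),
        batch_shifts={b: rng.normal(0.0, 0.3, size=n_genes) for b in design.batches},
    )


def simulate_treatment_experiment(
    design: TreatmentDesign,
    effects: EffectModel,
    seed: int,
    scale: str = "log2",
) -> tuple[ExpressionMatrix, SampleAnnotation, pd.DataFrame]:
    """Simulate the treatment experiment on the log2 scale.

    expression = baseline + batch shift + arm effect + N(0, noise_sd).
    With ``scale="raw_intensity"`` the log2 matrix is exponentiated so the
    preprocessing stages (background subtraction, quantile normalization,
    log transform) have realistic input.

    Returns (matrix, annotation, truth) where truth is the per-gene per-arm
    signed log2 effect table.
    """
    unknown = effects.referenced_arms() - set(design.arms)
    if unknown:
        raise ValueError(f"effect model references unknown arm(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    layout = design.layout()
    truth = effects.effect_table(design.arms)
    genes = list(truth.index)
    baseline = (
        effects.baseline if effects.baseline is not None else np.full(effects.n_genes, 8.0)
    )
    shifts = effects.batch_shifts or {
        b: rng.normal(0.0, effects.batch_sd, size=effects.n_genes) for b in design.batches
    }
    X = np.empty((effects.n_genes, len(layout)))
    for j, row in layout.iterrows():
        X[:, j] = (
            baseline
            + shifts[row["batch"]]
            + truth[row["arm"]].to_numpy()
            + rng.normal(0.0, effects.noise_sd, size=effects.n_genes)
        )
    if scale == "raw_intensity":
        X = np.exp2(X)
    frame = pd.DataFrame(X, index=genes, columns=list(layout["sample_id"]))
    return ExpressionMatrix(frame, scale=scale), SampleAnnotation(layout), truth


@dataclass
class CohortModel:
    """Latent-factor cohort: a 3-component infiltration mixture loading on an
    immune module and (with weight ``loading_ifn``) an interferon module.

    Per-gene loadings are jittered by Uniform(0.6, 1.4) at simulation time so
    the immune-restricted expression profiles carry between-sample structure
    beyond a rank-one shift.
    """

    n_samples: int = 500
    n_genes: int = 1000
    immune_idx: np.ndarray = field(default_factory=lambda: np.arange(0, 50))
    ifn_idx: np.ndarray = field(default_factory=lambda: np.arange(50, 100))
    mixture_locs: tuple[float, float, float] = (-2.0, 0.0, 2.0)
    mixture_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    within_sd: float = 0.4
    loading_immune: float = 1.0
    loading_ifn: float = 0.8
    noise_sd: float = 0.5
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        self.immune_idx = np.asarray(self.immune_idx, dtype=int)
        self.ifn_idx = np.asarray(self.ifn_idx, dtype=int)
        if self.immune_idx.size == 0 or self.ifn_idx.size == 0:
            raise ValueError("immune and ifn gene sets must be nonempty")
        if not self.allow_overlap and np.intersect1d(self.immune_idx, self.ifn_idx).size:
            raise ValueError(
                "immune and ifn gene sets overlap; pass allow_overlap=True to permit this"
            )
        if not (np.isfinite(self.loading_immune) and np.isfinite(self.loading_ifn)):
            raise ValueError("loadings must be finite")
        if not (self.mixture_locs[0] < self.mixture_locs[1] < self.mixture_locs[2]):
            raise ValueError("mixture locations must be strictly increasing")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")


GROUP_NAMES = ("low", "medium", "high")


def simulate_cohort(model: CohortModel, seed: int) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the cohort; truth holds each sample's latent infiltration
    value and mixture-component group label (low/medium/high)."""
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=model.n_samples, p=np.asarray(model.mixture_weights))
    locs = np.asarray(model.mixture_locs)
    a = locs[comp] + rng.normal(0.0, model.within_sd, size=model.n_samples)
    loadings = np.zeros(model.n_genes)
    jitter = rng.uniform(0.6, 1.4, size=model.n_genes)
    loadings[model.immune_idx] = model.loading_immune * jitter[model.immune_idx]
    loadings[model.ifn_idx] = model.loading_ifn * jitter[model.ifn_idx]
    baseline = rng.normal(8.0, 1.0, size=model.n_genes)
    X = (
        baseline[:, None]
        + loadings[:, None] * a[None, :]
        + rng.normal(0.0, model.noise_sd, size=(model.n_genes, model.n_samples))
    )
    genes = [f"G{i:05d}" for i in range(model.n_genes)]
    samples = [f"S{i:04d}" for i in range(model.n_samples)]
    matrix = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples), scale="log2")
    truth = pd.DataFrame(
        {
            "sample_id": samples,
            "infiltration": a,
            "group": [GROUP_NAMES[c] for c in comp],
        }
    )
    return matrix, truth


@dataclass
class SurvivalModel:
    """Exponential hazard: rate(s) = baseline_rate * exp(coef * score(s)),
    censored at min(independent Exp(censor_rate) draw, admin_time)."""

    baseline_rate: float = 0.05
    coef: float = 0.0
    admin_time: float = 120.0
    censor_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be positive")
        if self.admin_time <= 0:
            raise ValueError("administrative censoring time must be positive")
        if self.censor_rate < 0:
            raise ValueError("censoring rate must be non-negative")


def simulate_survival(
    scores: pd.Series | np.ndarray,
    model: SurvivalModel,
    seed: int,
    endpoint: str = "OS",
) -> SurvivalTable:
    """Draw one time-to-event record per score."""
    scores = pd.Series(scores)
    if len(scores) == 0:
        raise ValueError("empty score vector")
    vals = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("scores must be finite")
    rng = np.random.default_rng(seed)
    rates = model.baseline_rate * np.exp(model.coef * vals)
    t_event = rng.exponential(1.0 / rates)
    if model.censor_rate > 0:
        t_indep = rng.exponential(1.0 / model.censor_rate, size=len(vals))
    else:
        t_indep = np.full(len(vals), np.inf)
    t_cens = np.minimum(t_indep, model.admin_time)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    ids = [str(i) for i in scores.index] if scores.index.inferred_type != "integer" else [
        f"P{i:04d}" for i in range(len(vals))
    ]
    frame = pd.DataFrame(
        {"patient_id": ids, "time": time, "event": event, "endpoint": endpoint, "score": vals}
    )
    return SurvivalTable(frame)
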