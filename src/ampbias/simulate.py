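"""Synthetic probe-level data with the generative structure of the model.

Emulates an Affymetrix-style design: each probe set carries ~11 probes whose
positions concentrate within ~600 bp of the transcript's 3' end.  Observed
intensities follow

    PM_i = IPS_k * p_cycle(z_i) + eps_i

with Gaussian probe noise and truncation of negatives at 0 (chips do not
report negative intensities).  Two noise models are available:

``constant``  (default) — per probe set, sd = noise_frac * IPS_k, matching
the homoscedastic-within-set assumption of the correction model;
``proportional`` — sd = noise_frac * IPS_k * p(z_i), heteroscedastic noise
scaled to the degraded signal, closer to real chip behavior.

True intensities are log-normal on the log2 scale (mean 8, sd 1.5), the
canonical shape of microarray expression distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import DegradationParams, RetainingRateCurve, retaining_rate_curve

__all__ = ["SyntheticSpec", "generate_dataset", "generate_replicate_groups"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator; defaults are the reference conditions."""

    n_probe_sets: int = 20_000
    probes_per_set: int = 11
    L: float = 1000.0
    position_range: tuple[float, float] = (12.0, 600.0)
    log2_mean: float = 8.0
    log2_sd: float = 1.5
    params: DegradationParams = field(
        default_factory=lambda: DegradationParams(L=1000.0, a=300.0, b=200.0)
    )
    noise_frac: float = 0.1
    noise_model: str = "constant"
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probe_sets < 1 or self.probes_per_set < 1 or self.n_samples < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.position_range
        if not (0 <= lo < hi <= self.L):
            raise ValueError(f"position_range {self.position_range} not within [0, {self.L}]")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")
        if self.noise_model not in ("constant", "proportional"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.params.L != self.L:
            raise ValueError("spec.L and spec.params.L disagree")


def _curve_for(spec: SyntheticSpec, cycle: int) -> RetainingRateCurve:
    return retaining_rate_curve(spec.params, cycle, grid_step=2.0)


def _noise_sd(spec: SyntheticSpec, ips: np.ndarray, p: np.ndarray) -> np.ndarray:
    if spec.noise_model == "constant":
        return spec.noise_frac * ips
    return spec.noise_frac * ips * p


def generate_dataset(
    spec: SyntheticSpec,
    cycle: int = 2,
    curve: RetainingRateCurve | None = None,
    group_effects: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format probe table plus its ground truth.

    Returns ``(probes, truth)``: ``probes`` has columns
    ``sample_id, probeset_id, probe_id, z, pm, present``; ``truth`` adds the
    latent ``ips_true`` and per-probe ``p_true``.  Probe positions are drawn
    once per probe set and shared across samples, as on a physical chip.
    Deterministic given ``spec.seed``.

    ``group_effects`` (n_samples x n_probe_sets, multiplicative on IPS)
    supports replicate-group designs; defaults to 1.
    """
    rng = np.random.default_rng(spec.seed)
    curve = curve if curve is not None else _curve_for(spec, cycle)
    ns, npr, nsam = spec.n_probe_sets, spec.probes_per_set, spec.n_samples

    z = rng.uniform(*spec.position_range, size=(ns, npr))
    base_ips = 2.0 ** rng.normal(spec.log2_mean, spec.log2_sd, size=ns)
    p = np.asarray(curve(z))

    if group_effects is None:
        group_effects = np.ones((nsam, ns))
    group_effects = np.asarray(group_effects, dtype=float)
    if group_effects.shape != (nsam, ns):
        raise ValueError(f"group_effects must have shape {(nsam, ns)}")
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(nsam)]

    pset_ids = np.array([f"ps{k:05d}" for k in range(ns)])
    probe_ids = np.array([f"p{i + 1}" for i in range(npr)])

    probe_frames, truth_frames = [], []
    for j in range(nsam):
        ips = base_ips * group_effects[j]
        signal = ips[:, None] * p
        eps = rng.normal(0.0, 1.0, size=(ns, npr)) * _noise_sd(spec, ips[:, None], p)
        pm = signal + eps
        truncated = pm < 0
        pm = np.clip(pm, 0.0, None)
        frame = pd.DataFrame(
            {
                "sample_id": sample_ids[j],
                "probeset_id": np.repeat(pset_ids, npr),
                "probe_id": np.tile(probe_ids, ns),
                "z": z.ravel(),
                "pm": pm.ravel(),
                "present": 1,
            }
        )
        probe_frames.append(frame)
        truth_frames.append(
            frame.assign(
                p_true=p.ravel(),
                ips_true=np.repeat(ips, npr),
                truncated=truncated.ravel().astype(int),
            )[
                [
                    "sample_id",
                    "probeset_id",
                    "probe_id",
                    "z",
                    "p_true",
                    "ips_true",
                    "truncated",
                ]
            ]
        )
    return (
        pd.concat(probe_frames, ignore_index=True),
        pd.concat(truth_frames, ignore_index=True),
    )


def generate_replicate_groups(
    spec: SyntheticSpec,
    n_groups: int = 5,
    n_replicates: int = 3,
    group_effect_sd: float = 1.0,
    cycle: int = 2,
    curve: RetainingRateCurve | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Multi-sample design with replicate groups sharing expression profiles.

    Groups differ by per-probe-set multiplicative effects (log2-normal with
    sd ``group_effect_sd``); replicates within a group differ by probe noise
    only, so they correlate more strongly within than between groups as long
    as ``group_effect_sd > 0``.  Returns ``(probes, truth, sample_to_group)``
    with sample ids ``g<i>_r<j>``.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(spec.seed + 1)
    effects = 2.0 ** rng.normal(0.0, group_effect_sd, size=(n_groups, spec.n_probe_sets))
    group_effects = np.repeat(effects, n_replicates, axis=0)
    sample_ids = [
        f"g{g + 1}_r{r + 1}" for g in range(n_groups) for r in range(n_replicates)
    ]
    multi = replace(spec, n_samples=n_groups * n_replicates)
    probes, truth = generate_dataset(
        multi, cycle=cycle, curve=curve, group_effects=group_effects, sample_ids=sample_ids
    )
    mapping = {sid: sid.split("_")[0] for sid in sample_ids}
    return probes, truth, mapping
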