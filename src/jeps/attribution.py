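"""Shapley-value attribution for trained multimodal models.

Players are the clinical features plus volume blocks (cubic groups of
voxels, all channels toggling together; block edge 1 means per-voxel).
Attributions are estimated by permutation sampling against a baseline of
per-position training-set expectations: for each sampled permutation,
players are switched from their expected value to the patient's real
value one at a time, and each player is credited with the induced change
in the predicted probability.  The estimator is unbiased for the exact
Shapley values of the block-grouped game and satisfies the efficiency
axiom up to sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AttributionReport:
    patient_id: str
    clinical: np.ndarray                   # per-feature Shapley values
    volume_blocks: np.ndarray              # per-block Shapley values (3D grid)
    granularity: int
    n_samples: int
    seed: int

    @property
    def clinical_aggregate(self) -> float:
        return float(np.abs(self.clinical).sum())

    @property
    def volume_aggregate(self) -> float:
        return float(np.abs(self.volume_blocks).sum())


def baseline_expectations(train_inputs: dict) -> dict:
    """Per-position mean of every input over the training samples."""
    out = {}
    for key, arr in train_inputs.items():
        arr = np.asarray(arr)
        if arr.shape[0] < 1:
            raise ValueError("need at least one training sample")
        out[key] = arr.mean(axis=0)
    return out


def _volume_blocks(shape, granularity):
    d, h, w, _ = shape
    g = granularity
    blocks = []
    for z in range(0, d, g):
        for y in range(0, h, g):
            for x in range(0, w, g):
                blocks.append((slice(z, min(z + g, d)), slice(y, min(y + g, h)),
                               slice(x, min(x + g, w))))
    grid_shape = (-(-d // g), -(-h // g), -(-w // g))
    return blocks, grid_shape


def shapley_attribution(model, sample: dict, baseline: dict, n_samples: int = 128,
                        granularity: int = 4, seed: int = 0,
                        batch_evals: int = 64):
    """Permutation-sampling Shapley estimate for one patient.

    ``model`` must expose ``predict(batch) -> probabilities``; ``sample``
    and ``baseline`` hold unbatched inputs under the keys the model
    accepts ('clinical' and/or 'volume').
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)

    players = []                             # (kind, index or block slices)
    has_clin = "clinical" in sample
    has_vol = "volume" in sample
    if has_clin:
        n_clin = np.asarray(sample["clinical"]).size
        players += [("clinical", j) for j in range(n_clin)]
    if has_vol:
        blocks, grid_shape = _volume_blocks(np.asarray(sample["volume"]).shape,
                                            granularity)
        players += [("volume", bi) for bi in range(len(blocks))]
    n_players = len(players)

    clin_attr = np.zeros(n_clin) if has_clin else np.zeros(0)
    vol_attr = np.zeros(len(blocks)) if has_vol else np.zeros(0)

    def eval_states(states):
        """Model outputs for a list of per-player on/off state vectors."""
        batches = {k: [] for k in sample}
        for st in states:
            cur = {k: np.array(baseline[k], dtype=float, copy=True) for k in sample}
            for pi in np.flatnonzero(st):
                kind, loc = players[pi]
                if kind == "clinical":
                    cur["clinical"].ravel()[loc] = np.asarray(sample["clinical"]).ravel()[loc]
                else:
                    cur["volume"][blocks[loc]] = np.asarray(sample["volume"])[blocks[loc]]
            for k in sample:
                batches[k].append(cur[k])
        out = []
        for start in range(0, len(states), batch_evals):
            batch = {k: np.stack(v[start:start + batch_evals])
                     for k, v in batches.items()}
            out.append(model.predict(batch))
        return np.concatenate(out)

    for _ in range(n_samples):
        perm = rng.permutation(n_players)
        states = np.zeros((n_players + 1, n_players), dtype=bool)
        for step, pi in enumerate(perm):
            states[step + 1] = states[step]
            states[step + 1, pi] = True
        preds = eval_states(list(states))
        deltas = np.diff(preds)
        for step, pi in enumerate(perm):
            kind, loc = players[pi]
            if kind == "clinical":
                clin_attr[loc] += deltas[step]
            else:
                vol_attr[loc] += deltas[step]

    clin_attr /= n_samples
    vol_attr /= n_samples
    result = {}
    if has_clin:
        result["clinical"] = clin_attr
    if has_vol:
        result["volume_blocks"] = vol_attr.reshape(grid_shape)
        result["grid_shape"] = grid_shape
    return result


def attribute_patient(model, sample, baseline, patient_id="", n_samples=128,
                      granularity=4, seed=0) -> AttributionReport:
    res = shapley_attribution(model, sample, baseline, n_samples, granularity, seed)
    return AttributionReport(
        patient_id=patient_id,
        clinical=res.get("clinical", np.zeros(0)),
        volume_blocks=res.get("volume_blocks", np.zeros((0, 0, 0))),
        granularity=granularity, n_samples=n_samples, seed=seed)


def modality_influence(report: AttributionReport) -> tuple[float, float]:
    """(clinical, volume) summed absolute Shapley influence."""
    return report.clinical_aggregate, report.volume_aggregate


def modality_log_ratio(report: AttributionReport, eps: float = 1e-12) -> float:
    """log10 of volume/clinical influence; 0 means perfectly balanced."""
    return float(np.log10((report.volume_aggregate + eps)
                          / (report.clinical_aggregate + eps)))


def voxel_heatmap(reports: list[AttributionReport]):
    """Mean attribution volume over patients plus three flattened views."""
    if not reports:
        raise ValueError("need at least one report")
    gran = {r.granularity for r in reports}
    shapes = {r.volume_blocks.shape for r in reports}
    if len(gran) != 1 or len(shapes) != 1:
        raise ValueError("reports have mixed granularities or grids")
    mean_vol = np.mean([r.volume_blocks for r in reports], axis=0)
    views = {axis_name: mean_vol.mean(axis=ax)
             for ax, axis_name in enumerate(("axial", "coronal", "sagittal"))}
    return mean_vol, views


def exact_shapley(model, sample: dict, baseline: dict, granularity: int = 1):
    """Exact Shapley values by full subset enumeration (test oracle;
    feasible only for small player counts)."""
    from itertools import combinations
    from math import factorial

    players = []
    if "clinical" in sample:
        players += [("clinical", j) for j in range(np.asarray(sample["clinical"]).size)]
    blocks = []
    if "volume" in sample:
        blocks, grid = _volume_blocks(np.asarray(sample["volume"]).shape, granularity)
        players += [("volume", b) for b in blocks]
    n = len(players)
    if n > 20:
        raise ValueError("exact enumeration limited to 20 players")

    def value(subset):
        cur = {k: np.array(baseline[k], dtype=float, copy=True) for k in sample}
        for pi in subset:
            kind, loc = players[pi]
            if kind == "clinical":
                cur["clinical"].ravel()[loc] = np.asarray(sample["clinical"]).ravel()[loc]
            else:
                cur["volume"][loc] = np.asarray(sample["volume"])[loc]
        batch = {k: v[None] for k, v in cur.items()}
        return float(model.predict(batch)[0])

    vals = {}
    for r in range(n + 1):
        for sub in combinations(range(n), r):
            vals[sub] = value(sub)
    phi = np.zeros(n)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        for r in range(n):
            for sub in combinations(others, r):
                w = factorial(r) * factorial(n - r - 1) / factorial(n)
                phi[i] += w * (vals[tuple(sorted(sub + (i,)))] - vals[sub])
    out = {}
    if "clinical" in sample:
        nc = np.asarray(sample["clinical"]).size
        out["clinical"] = phi[:nc]
        phi = phi[nc:]
    if "volume" in sample:
        out["volume_blocks"] = phi.reshape(grid)
    return out
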