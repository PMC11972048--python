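"""Cross-validated training protocol with strict per-fold preprocessing.

The cohort is split into stratified folds; for every fold, the clinical
encoder and the radiomics variance filter are fitted on that fold's
training rows only, every design is trained (or fitted) on the same
train rows and scored on the same test rows, and volume inputs receive
on-line augmentation (2/3 probability per volume per epoch: zoom 0.8-1.2,
in-plane rotation up to 15 degrees, or in-plane shift up to 20%).
Networks minimize weighted binary cross-entropy (positives overweighted
2:1) with Adam, learning-rate reduction on validation plateau, early
stopping, and best-weight restoration.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import architectures as arch
from .nn.optim import Adam, weighted_bce, weighted_bce_grad_logits
from .phantom import CLINICAL_SCHEMA
from .radiomics import (FeatureVector, build_early_fusion_vector,
                        extract_radiomics, fit_variance_filter)
from .stats import FoldResult
from .tabular import ClinicalSchema, encode_clinical, fit_clinical_encoder
from .volume import StructureSet, VoxelGrid, preprocess_patient


@dataclass
class TrainConfig:
    """Training protocol settings (defaults follow the study protocol)."""

    batch_size: int = 25
    learning_rate: float = 1e-3
    lr_factor: float = 0.5
    lr_patience: int = 20
    lr_floor: float = 1e-5
    early_stop_patience: int = 60
    pos_weight: float = 2.0
    augment_prob: float = 2.0 / 3.0
    max_epochs: int = 500
    val_fraction: float = 0.1
    seed: int = 0


def micro_train_config(seed: int = 0) -> TrainConfig:
    """Shortened schedule paired with the micro phantom profile: 32 epochs,
    initial LR 3e-3 with plateau halving, suited to minute-scale CPU runs."""
    return TrainConfig(max_epochs=32, early_stop_patience=32, lr_patience=12,
                       learning_rate=3e-3, seed=seed)


@dataclass
class FoldPlan:
    k: int
    test_ids: list[list[str]]
    val_ids: list[list[str]]
    seed: int

    def train_ids(self, fold: int, all_ids: list[str]) -> list[str]:
        test = set(self.test_ids[fold])
        return [i for i in all_ids if i not in test]


def make_folds(labels, k: int, seed: int, ids=None,
               val_fraction: float = 0.1) -> FoldPlan:
    """Stratified fold assignment: seeded shuffle within each class, then
    round-robin.  Keyed by patient id so cohort row order is irrelevant."""
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if k > n:
        raise ValueError(f"k={k} exceeds cohort size {n}")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for stratified folds")
    ids = [str(i) for i in (ids if ids is not None else range(n))]
    order = np.argsort(np.array(ids))        # canonical order, row-order free
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    cursor = 0                               # carried across classes so the
    for cls in (1, 0):                       # remainder spreads over folds
        members = [ids[i] for i in order if labels[i] == cls]
        if 0 < len(members) < k:
            warnings.warn(f"class {cls} has fewer members ({len(members)}) than folds")
        perm = rng.permutation(len(members))
        for mi in perm:
            folds[cursor % k].append(members[mi])
            cursor += 1
    label_of = dict(zip(ids, labels))
    val_ids = []
    for f in range(k):
        test = set(folds[f])
        train = [i for i in sorted(ids) if i not in test]
        vrng = np.random.default_rng(seed * 1000 + f + 1)
        chosen = []
        for cls in (1, 0):
            members = [i for i in train if label_of[i] == cls]
            n_val = max(1, int(round(val_fraction * len(members))))
            pick = vrng.permutation(len(members))[:n_val]
            chosen.extend(members[j] for j in pick)
        val_ids.append(sorted(chosen))
    return FoldPlan(k=k, test_ids=[sorted(f) for f in folds], val_ids=val_ids, seed=seed)


def augment_volume(vol: np.ndarray, rng: np.random.Generator,
                   augment_prob: float = 2.0 / 3.0) -> np.ndarray:
    """With probability ``augment_prob``, apply one randomly chosen geometric
    operation (3D zoom 0.8-1.2, axial-plane rotation +/-15 deg, or in-plane
    shift up to 20% of extent).  CT/dose interpolate linearly, the mask
    nearest-neighbor; the shape is unchanged and exposed regions are 0."""
    if rng.random() >= augment_prob:
        return vol
    op = rng.integers(3)
    d, h, w, _ = vol.shape
    center = np.array([(d - 1) / 2, (h - 1) / 2, (w - 1) / 2])
    mat = np.eye(3)
    shift = np.zeros(3)
    if op == 0:                               # zoom
        f = rng.uniform(0.8, 1.2)
        mat = np.eye(3) / f
    elif op == 1:                             # axial-plane rotation
        th = np.deg2rad(rng.uniform(-15.0, 15.0))
        c, s = np.cos(th), np.sin(th)
        mat = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    else:                                     # in-plane shift
        shift = np.array([0.0,
                          rng.uniform(-0.2, 0.2) * h,
                          rng.uniform(-0.2, 0.2) * w])
    offset = center - mat @ (center + shift)
    out = np.empty_like(vol)
    for c_idx, order in ((0, 1), (1, 1), (2, 0)):
        out[..., c_idx] = ndimage.affine_transform(
            vol[..., c_idx].astype(float), mat, offset=offset, order=order,
            mode="constant", cval=0.0).astype(vol.dtype)
    return out


@dataclass
class PreparedCohort:
    """Per-patient model-ready inputs shared by every design and fold."""

    ids: list[str]
    labels: np.ndarray
    times: np.ndarray
    events: np.ndarray
    records: list[dict]
    volumes: np.ndarray                      # (N, D, H, W, 3)
    radiomics: list[FeatureVector]
    schema: ClinicalSchema
    true_risk: np.ndarray | None = None

    def index_of(self, ids) -> np.ndarray:
        pos = {pid: i for i, pid in enumerate(self.ids)}
        return np.array([pos[i] for i in ids], dtype=int)


def prepare_cohort(patients, spacing_mm, window) -> PreparedCohort:
    """Run the volume pipeline and radiomics extraction for every patient."""
    vols, feats, records = [], [], []
    for p in patients:
        ct = VoxelGrid(p.ct_volume, spacing_mm)
        dose = VoxelGrid(p.dose_volume, spacing_mm)
        ss = StructureSet(p.structures)
        vol, ct_raw, mask = preprocess_patient(
            ct, dose, ss, p.ipsilateral_side, target_spacing=spacing_mm,
            window=window, patient_id=p.patient_id, return_raw=True)
        vols.append(vol.values)
        feats.append(extract_radiomics(ct_raw.values, mask.values, spacing_mm))
        records.append(dict(p.clinical))
    return PreparedCohort(
        ids=[p.patient_id for p in patients],
        labels=np.array([p.label_2yr for p in patients]),
        times=np.array([p.survival_months for p in patients]),
        events=np.array([p.event for p in patients]),
        records=records,
        volumes=np.stack(vols).astype(np.float32),
        radiomics=feats,
        schema=ClinicalSchema.from_dict(CLINICAL_SCHEMA),
        true_risk=np.array([p.true_risk for p in patients]),
    )


def _stratified_split(labels, val_fraction, rng):
    idx = np.arange(labels.size)
    val = []
    for cls in np.unique(labels):
        members = idx[labels == cls]
        n_val = max(1, int(round(val_fraction * members.size)))
        val.extend(rng.permutation(members)[:n_val])
    val = np.sort(np.array(val))
    train = np.setdiff1d(idx, val)
    return train, val


def train_network(model, train_batch: dict, y_train, val_batch: dict, y_val,
                  config: TrainConfig, rng: np.random.Generator,
                  augment: bool = True) -> dict:
    """Optimize weighted BCE with Adam, plateau LR reduction, early stopping
    and best-weight restoration.  Returns the training history."""
    if y_val.size == 0:
        raise ValueError("empty validation split")
    opt = Adam(model.params(), lr=config.learning_rate)
    n = y_train.size
    best_loss, best_weights, best_epoch = np.inf, model.get_weights(), -1
    since_improve, since_lr = 0, 0
    history = {"train_loss": [], "val_loss": [], "lr": []}
    y_tr = y_train.astype(np.float32)[:, None]
    y_va = y_val.astype(np.float32)[:, None]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            batch = {}
            for key, arr in train_batch.items():
                sub = arr[sel]
                if key == "volume" and augment:
                    sub = np.stack([augment_volume(v, rng, config.augment_prob)
                                    for v in sub])
                batch[key] = sub
            p = model.forward(batch, training=True)
            ep_loss += weighted_bce(p, y_tr[sel], config.pos_weight) * sel.size
            opt.zero_grad()
            model.backward_logits(weighted_bce_grad_logits(p, y_tr[sel], config.pos_weight))
            opt.step()
        p_val = model.forward(val_batch, training=False)
        val_loss = weighted_bce(p_val, y_va, config.pos_weight)
        history["train_loss"].append(ep_loss / n)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < best_loss - 1e-6:
            best_loss, best_weights, best_epoch = val_loss, model.get_weights(), epoch
            since_improve = since_lr = 0
        else:
            since_improve += 1
            since_lr += 1
            if since_improve >= config.early_stop_patience:
                break
            if since_lr >= config.lr_patience and opt.lr > config.lr_floor:
                opt.lr = max(opt.lr * config.lr_factor, config.lr_floor)
                since_lr = 0
    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_loss
    return history


def _fold_inputs(cohort: PreparedCohort, plan: FoldPlan, fold: int):
    """Index sets plus fold-local (leakage-safe) encoders and matrices."""
    test_idx = cohort.index_of(plan.test_ids[fold])
    val_idx = cohort.index_of(plan.val_ids[fold])
    train_all = cohort.index_of(plan.train_ids(fold, cohort.ids))
    fit_idx = np.setdiff1d(train_all, val_idx)

    encoder = fit_clinical_encoder([cohort.records[i] for i in train_all],
                                   cohort.schema)
    clin = encode_clinical(cohort.records, encoder)
    vfilter = fit_variance_filter([cohort.radiomics[i] for i in train_all])
    early = np.stack([
        build_early_fusion_vector(cohort.radiomics[i], clin[i], vfilter)
        for i in range(len(cohort.ids))])
    return dict(test=test_idx, val=val_idx, fit=fit_idx, train_all=train_all,
                encoder=encoder, clinical=clin, early=early, vfilter=vfilter)


def train_fold(design: str, cohort: PreparedCohort, fold_io: dict,
               config: TrainConfig, fold: int,
               model_cache: dict | None = None):
    """Train/fit one design on one fold; returns test scores (and caches
    single-modality models reused by the late-average composition)."""
    fit, val, test = fold_io["fit"], fold_io["val"], fold_io["test"]
    labels = cohort.labels
    clin, early = fold_io["clinical"], fold_io["early"]
    vol = cohort.volumes
    rng = np.random.default_rng(
        (config.seed, fold, zlib.crc32(design.encode()) % (2 ** 16)))

    def network(spec_design, inputs, augment):
        spec = arch.ModelSpec(
            spec_design,
            clinical_width=inputs["clinical"].shape[1] if "clinical" in inputs else 1,
            volume_shape=vol.shape[1:] if "volume" in inputs else (8, 8, 8, 3),
            seed=config.seed * 10000 + fold)
        model = arch.build(spec)
        train_network(model,
                      {k: a[fit] for k, a in inputs.items()}, labels[fit],
                      {k: a[val] for k, a in inputs.items()}, labels[val],
                      config, rng, augment=augment)
        return model

    if design == "cph_clinical":
        scorer = arch.build_cph_baseline(clin[fit], cohort.times[fit], cohort.events[fit])
        return scorer.risk(clin[test])
    if design == "early_cph":
        scorer = arch.build_cph_baseline(early[fit], cohort.times[fit], cohort.events[fit])
        return scorer.risk(early[test])
    if design == "mlp_clinical":
        model = network("mlp_clinical", {"clinical": clin}, augment=False)
        return model.predict({"clinical": clin[test]})
    if design == "early_mlp":
        model = network("early_mlp", {"clinical": early}, augment=False)
        return model.predict({"clinical": early[test]})
    if design == "resnet_volume":
        model = network("resnet_volume", {"volume": vol}, augment=True)
        if model_cache is not None:
            model_cache["resnet_volume"] = model
        return model.predict({"volume": vol[test]})
    if design == "joint_late":
        model = network("joint_late", {"volume": vol, "clinical": clin}, augment=True)
        if model_cache is not None:
            model_cache["joint_late"] = model
        return model.predict({"volume": vol[test], "clinical": clin[test]})
    if design == "jeps":
        model = network("jeps", {"volume": vol, "clinical": clin}, augment=True)
        if model_cache is not None:
            model_cache["jeps"] = model
        return model.predict({"volume": vol[test], "clinical": clin[test]})
    if design == "late_average":
        cache = model_cache if model_cache is not None else {}
        if "mlp_clinical_model" not in cache:
            cache["mlp_clinical_model"] = network("mlp_clinical", {"clinical": clin},
                                                  augment=False)
        if "resnet_volume" not in cache:
            cache["resnet_volume"] = network("resnet_volume", {"volume": vol},
                                             augment=True)
        p_c = cache["mlp_clinical_model"].predict({"clinical": clin[test]})
        p_v = cache["resnet_volume"].predict({"volume": vol[test]})
        return arch.late_fusion_average(p_c, p_v)
    raise ValueError(f"unknown design {design!r}")


def run_cross_validation(cohort: PreparedCohort, designs, plan: FoldPlan,
                         config: TrainConfig,
                         collect_models: dict | None = None) -> list[FoldResult]:
    """Train and score every design on every fold of the shared plan."""
    results = []
    for fold in range(plan.k):
        try:
            io = _fold_inputs(cohort, plan, fold)
            cache: dict = {}
            for design in designs:
                scores = train_fold(design, cohort, io, config, fold, cache)
                test_ids = plan.test_ids[fold]
                results.append(FoldResult(design, fold, test_ids,
                                          np.asarray(scores, dtype=float),
                                          cohort.labels[io["test"]]))
            if collect_models is not None:
                collect_models[fold] = {"models": cache, "io": io}
        except Exception as e:
            raise RuntimeError(f"cross-validation failed at fold {fold}: {e}") from e
    return results
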