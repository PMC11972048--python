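"""The seven model designs and their parameter accounting.

The volumetric backbone is a 3-D CNN in the ResNet-18 pattern: a strided
stem convolution plus max-pooling (together reducing each spatial axis by
4x), four stages of two basic residual blocks with 16/32/64/128 filters,
global average pooling, and a dense head that narrows to a flat length-16
volume embedding before the sigmoid output.  The two joint designs differ
only in where the clinical embedding enters this backbone:

* ``joint_late`` concatenates the length-16 clinical embedding with the
  length-16 volume embedding after all spatial processing (post-flatten).
* ``jeps`` (joint early pre-spatial) projects the clinical embedding to a
  ``1 x 1 x 1 x 16`` tensor, repeats it across the post-stem spatial grid,
  and concatenates it on the channels axis *before* the residual stages,
  so clinical information can steer spatial feature extraction directly.

Exact layer hyperparameters (stem kernel 5^3, biased un-normalized
projection shortcuts, head widths 72/60/16, fusion MLP widths 78/32/16,
the extra dense layer in the JEPS upsampler) were calibrated so that the
three reference builds reproduce the published totals of 2 094 341,
2 104 243 and 2 111 427 trainable parameters; see ``docs/methods.md``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn.layers import (F32, BatchNorm, Conv3D, Dense, Dropout, GlobalAvgPool,
                        Layer, MaxPool3D, Param, ReLU, Sequential, Sigmoid)

DESIGNS = ("cph_clinical", "mlp_clinical", "resnet_volume", "early_cph",
           "early_mlp", "late_average", "joint_late", "jeps")

FUSION_POINTS = {
    "cph_clinical": "none", "mlp_clinical": "none", "resnet_volume": "none",
    "early_cph": "input_level", "early_mlp": "input_level",
    "late_average": "output_level",
    "joint_late": "post_flatten", "jeps": "pre_spatial",
}

#: Calibrated reference configuration reproducing the published parameter
#: totals (clinical encoded width 80, paper-scale volume input).
REFERENCE_CLINICAL_WIDTH = 80
REFERENCE_VOLUME_SHAPE = (90, 128, 128, 3)

STAGE_WIDTHS = (16, 32, 64, 128)
STEM_FILTERS = 16
STEM_KERNEL = 5
HEAD_WIDTHS = (72, 60)
EMBEDDING_LEN = 16
FUSION_MLP_WIDTHS = (78, 32)


@dataclass
class ModelSpec:
    """Declarative description of one architecture."""

    design: str
    clinical_width: int = REFERENCE_CLINICAL_WIDTH
    volume_shape: tuple[int, int, int, int] = REFERENCE_VOLUME_SHAPE
    embedding_len: int = EMBEDDING_LEN
    dropout: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; choose from {DESIGNS}")
        if self.embedding_len <= 0:
            raise ValueError("embedding length must be positive")
        if self.design in ("resnet_volume", "joint_late", "jeps", "late_average"):
            if len(self.volume_shape) != 4 or self.volume_shape[-1] != 3:
                raise ValueError("volume designs require a 4D input shape with 3 channels")

    @property
    def fusion_point(self) -> str:
        return FUSION_POINTS[self.design]


def post_stem_shape(volume_shape: tuple[int, ...]) -> tuple[int, int, int]:
    """Spatial shape after the stem conv (stride 2) and max-pool (stride 2)."""
    d, h, w = volume_shape[:3]
    return (-(-d // 4), -(-h // 4), -(-w // 4))


def broadcast_embedding(embedding: np.ndarray, spatial_shape: tuple[int, int, int]) -> np.ndarray:
    """Repeat a length-E embedding across a spatial grid (channels axis last)."""
    emb = np.asarray(embedding)
    if any(s <= 0 for s in spatial_shape):
        raise ValueError(f"spatial dimensions must be positive, got {spatial_shape}")
    e = emb.shape[-1]
    if e <= 0:
        raise ValueError("embedding length must be positive")
    if emb.ndim == 1:
        out = np.broadcast_to(emb, (*spatial_shape, e))
    else:
        out = np.broadcast_to(emb[:, None, None, None, :], (emb.shape[0], *spatial_shape, e))
    return np.ascontiguousarray(out)


def late_fusion_average(p_clinical, p_volume):
    """Arithmetic mean of two single-modality probabilities."""
    pc, pv = np.asarray(p_clinical, dtype=float), np.asarray(p_volume, dtype=float)
    if ((pc < 0) | (pc > 1)).any() or ((pv < 0) | (pv > 1)).any():
        raise ValueError("late-fusion inputs must be probabilities in [0, 1]")
    return (pc + pv) / 2.0


class BasicBlock(Layer):
    """Two 3^3 conv+BN layers with a residual shortcut (post-activation).

    A 1^3 projection convolution (bias, no normalization) is used whenever
    the shortcut must change resolution or channel count.
    """

    def __init__(self, c_in: int, c_out: int, stride: int, rng, name: str):
        self.conv1 = Conv3D(c_in, c_out, 3, stride, rng, f"{name}.conv1")
        self.bn1 = BatchNorm(c_out, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv3D(c_out, c_out, 3, 1, rng, f"{name}.conv2")
        self.bn2 = BatchNorm(c_out, name=f"{name}.bn2")
        self.relu_out = ReLU()
        self.proj = (Conv3D(c_in, c_out, 1, stride, rng, f"{name}.proj")
                     if stride != 1 or c_in != c_out else None)

    def params(self):
        ps = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, training=False):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training))
        out = self.bn2.forward(self.conv2.forward(out, training), training)
        sc = x if self.proj is None else self.proj.forward(x, training)
        return self.relu_out.forward(out + sc)

    def backward(self, dy):
        dy = self.relu_out.backward(dy)
        d_main = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(dy)))))
        d_sc = dy if self.proj is None else self.proj.backward(dy)
        return d_main + d_sc


def _make_stem(rng):
    return Sequential([
        Conv3D(3, STEM_FILTERS, STEM_KERNEL, 2, rng, "stem", input_grad=False),
        BatchNorm(STEM_FILTERS, name="stem.bn"),
        ReLU(),
        MaxPool3D(3, 2),
    ])


def _make_stages(rng, stage1_in: int):
    blocks, c_in = [], stage1_in
    for i, w in enumerate(STAGE_WIDTHS):
        stride = 1 if i == 0 else 2
        blocks.append(BasicBlock(c_in, w, stride, rng, f"stage{i + 1}.block1"))
        blocks.append(BasicBlock(w, w, 1, rng, f"stage{i + 1}.block2"))
        c_in = w
    return Sequential(blocks)


def _make_head(rng):
    """GAP -> 72 -> 60 -> 16 volume embedding (ReLU between layers)."""
    return Sequential([
        GlobalAvgPool(),
        Dense(STAGE_WIDTHS[-1], HEAD_WIDTHS[0], rng, "head.d1"), ReLU(),
        Dense(HEAD_WIDTHS[0], HEAD_WIDTHS[1], rng, "head.d2"), ReLU(),
        Dense(HEAD_WIDTHS[1], EMBEDDING_LEN, rng, "head.emb"), ReLU(),
    ])


def _make_fusion_mlp(spec: ModelSpec, rng):
    """Clinical branch shared by both joint designs: dense layers with
    incremental size reductions, interleaved with dropout, ending at the
    length-16 embedding."""
    if spec.clinical_width <= 0:
        raise ValueError("clinical input width must be positive")
    w1, w2 = FUSION_MLP_WIDTHS
    return Sequential([
        Dense(spec.clinical_width, w1, rng, "clin.d1"), ReLU(), Dropout(spec.dropout, rng),
        Dense(w1, w2, rng, "clin.d2"), ReLU(), Dropout(spec.dropout, rng),
        Dense(w2, EMBEDDING_LEN, rng, "clin.emb"), ReLU(),
    ])


def _check_volume_size(volume_shape):
    if min(post_stem_shape(volume_shape)) < 1 or min(volume_shape[:3]) < 4:
        raise ValueError(
            f"volume input {volume_shape} too small for four downsamplings")


class _BaseModel:
    """Shared plumbing: parameter list, weight snapshots, prediction."""

    out_sigmoid: Sigmoid

    def params(self) -> list[Param]:
        raise NotImplementedError

    def forward(self, batch: dict, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward_logits(self, dz: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the pre-sigmoid logits."""
        raise NotImplementedError

    def predict(self, batch: dict) -> np.ndarray:
        return self.forward(batch, training=False)[:, 0]

    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights):
            p.value[...] = w

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())


class ClinicalMLP(_BaseModel):
    """Clinical-only MLP: hidden layers 64, 32 and 16, dropout-interleaved."""

    HIDDEN = (64, 32, 16)

    def __init__(self, spec: ModelSpec):
        if spec.clinical_width <= 0:
            raise ValueError("clinical input width must be positive")
        rng = np.random.default_rng(spec.seed)
        layers, prev = [], spec.clinical_width
        for h in self.HIDDEN:
            layers += [Dense(prev, h, rng, f"mlp.d{h}"), ReLU(), Dropout(spec.dropout, rng)]
            prev = h
        self.body = Sequential(layers)
        self.out = Dense(prev, 1, rng, "mlp.out")
        self.out_sigmoid = Sigmoid()
        self.hidden_sizes = self.HIDDEN

    def params(self):
        return self.body.params() + self.out.params()

    def forward(self, batch, training=False):
        x = np.asarray(batch["clinical"], dtype=F32)
        return self.out_sigmoid.forward(self.out.forward(self.body.forward(x, training), training))

    def backward_logits(self, dz):
        self.body.backward(self.out.backward(dz))


class VolumeResNet(_BaseModel):
    """Volume-only 3D ResNet baseline."""

    def __init__(self, spec: ModelSpec):
        _check_volume_size(spec.volume_shape)
        rng = np.random.default_rng(spec.seed)
        self.stem = _make_stem(rng)
        self.stages = _make_stages(rng, STEM_FILTERS)
        self.head = _make_head(rng)
        self.out = Dense(EMBEDDING_LEN, 1, rng, "out")
        self.out_sigmoid = Sigmoid()

    def params(self):
        return (self.stem.params() + self.stages.params()
                + self.head.params() + self.out.params())

    def stem_activation(self, volume):
        """Post-stem activation (the JEPS fusion point shape)."""
        return self.stem.forward(np.asarray(volume, dtype=F32))

    def forward(self, batch, training=False):
        v = np.asarray(batch["volume"], dtype=F32)
        x = self.head.forward(self.stages.forward(self.stem.forward(v, training), training), training)
        return self.out_sigmoid.forward(self.out.forward(x, training))

    def backward_logits(self, dz):
        self.stem.backward(self.stages.backward(self.head.backward(self.out.backward(dz))))


class JointLateFusion(_BaseModel):
    """Joint fusion at the post-flatten point: the two length-16 embeddings
    are concatenated (width 32) and a joint dense head predicts."""

    def __init__(self, spec: ModelSpec):
        _check_volume_size(spec.volume_shape)
        rng = np.random.default_rng(spec.seed)
        self.stem = _make_stem(rng)
        self.stages = _make_stages(rng, STEM_FILTERS)
        self.head = _make_head(rng)
        self.clinical = _make_fusion_mlp(spec, rng)
        self.joint = Dense(2 * EMBEDDING_LEN, EMBEDDING_LEN, rng, "joint")
        self.joint_relu = ReLU()
        self.out = Dense(EMBEDDING_LEN, 1, rng, "out")
        self.out_sigmoid = Sigmoid()

    def params(self):
        return (self.stem.params() + self.stages.params() + self.head.params()
                + self.clinical.params() + self.joint.params() + self.out.params())

    def forward(self, batch, training=False):
        v = np.asarray(batch["volume"], dtype=F32)
        c = np.asarray(batch["clinical"], dtype=F32)
        v_emb = self.head.forward(self.stages.forward(self.stem.forward(v, training), training), training)
        c_emb = self.clinical.forward(c, training)
        fused = np.concatenate([v_emb, c_emb], axis=1)
        x = self.joint_relu.forward(self.joint.forward(fused, training))
        return self.out_sigmoid.forward(self.out.forward(x, training))

    def backward_logits(self, dz):
        dfused = self.joint.backward(self.joint_relu.backward(self.out.backward(dz)))
        dv, dc = dfused[:, :EMBEDDING_LEN], dfused[:, EMBEDDING_LEN:]
        self.stem.backward(self.stages.backward(self.head.backward(dv)))
        self.clinical.backward(dc)


class JEPSFusion(_BaseModel):
    """Joint early pre-spatial fusion.

    The clinical embedding passes through an upsampler (an extra dense
    projection, reshape to 1x1x1x16, spatial repeat) and is concatenated
    on the channels axis with the post-stem volume activation, so every
    subsequent convolution sees both modalities.
    """

    def __init__(self, spec: ModelSpec):
        _check_volume_size(spec.volume_shape)
        rng = np.random.default_rng(spec.seed)
        self.spatial = post_stem_shape(spec.volume_shape)
        self.stem = _make_stem(rng)
        self.stages = _make_stages(rng, STEM_FILTERS + EMBEDDING_LEN)
        self.head = _make_head(rng)
        self.clinical = _make_fusion_mlp(spec, rng)
        self.ups = Dense(EMBEDDING_LEN, EMBEDDING_LEN, rng, "ups")
        self.ups_relu = ReLU()
        self.out = Dense(EMBEDDING_LEN, 1, rng, "out")
        self.out_sigmoid = Sigmoid()

    def params(self):
        return (self.stem.params() + self.stages.params() + self.head.params()
                + self.clinical.params() + self.ups.params() + self.out.params())

    def forward(self, batch, training=False):
        v = np.asarray(batch["volume"], dtype=F32)
        c = np.asarray(batch["clinical"], dtype=F32)
        s = self.stem.forward(v, training)
        c_emb = self.ups_relu.forward(self.ups.forward(self.clinical.forward(c, training), training))
        tiled = broadcast_embedding(c_emb, s.shape[1:4]).astype(F32)
        fused = np.concatenate([s, tiled], axis=-1)
        x = self.head.forward(self.stages.forward(fused, training), training)
        return self.out_sigmoid.forward(self.out.forward(x, training))

    def backward_logits(self, dz):
        dfused = self.stages.backward(self.head.backward(self.out.backward(dz)))
        ds = dfused[..., :STEM_FILTERS]
        dtiled = dfused[..., STEM_FILTERS:]
        self.stem.backward(np.ascontiguousarray(ds))
        dc_emb = dtiled.sum(axis=(1, 2, 3))         # adjoint of the spatial repeat
        self.clinical.backward(self.ups.backward(self.ups_relu.backward(dc_emb)))


def build_clinical_mlp(spec: ModelSpec) -> ClinicalMLP:
    return ClinicalMLP(spec)


def build_volume_resnet(spec: ModelSpec) -> VolumeResNet:
    return VolumeResNet(spec)


def build_joint_late_fusion(spec: ModelSpec) -> JointLateFusion:
    return JointLateFusion(spec)


def build_jeps(spec: ModelSpec) -> JEPSFusion:
    return JEPSFusion(spec)


def count_parameters(model) -> int:
    """Total trainable parameters of a built model."""
    if hasattr(model, "n_parameters"):
        return model.n_parameters()
    return sum(p.size for p in model.params())


class CoxRiskScorer:
    """Proportional-hazards risk scorer: the fitted linear predictor."""

    def __init__(self, fitter, columns, keep):
        self._fitter = fitter
        self._columns = list(columns)
        self._keep = np.asarray(keep)

    @property
    def coefficients(self):
        return self._fitter.params_.to_numpy()

    def risk(self, x: np.ndarray) -> np.ndarray:
        import pandas as pd
        x = np.asarray(x, dtype=float)[:, self._keep]
        df = pd.DataFrame(x, columns=self._columns)
        return self._fitter.predict_partial_hazard(df).to_numpy()


def build_cph_baseline(clinical: np.ndarray, times: np.ndarray, events: np.ndarray,
                       penalizer: float = 0.1) -> CoxRiskScorer:
    """Fit a ridge-penalized Cox proportional-hazards model (lifelines)."""
    import pandas as pd
    from lifelines import CoxPHFitter

    events = np.asarray(events)
    if events.sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    x = np.asarray(clinical, dtype=float)
    keep = x.std(axis=0) > 0                 # constant columns break the fit
    x = x[:, keep]
    cols = [f"x{i}" for i in range(x.shape[1])]
    df = pd.DataFrame(x, columns=cols)
    df["time"] = np.asarray(times, dtype=float)
    df["event"] = events.astype(int)
    pen = penalizer
    for attempt in range(4):
        try:
            cph = CoxPHFitter(penalizer=pen)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            if attempt > 0:
                warnings.warn(f"Cox design ill-conditioned; penalizer raised to {pen}")
            return CoxRiskScorer(cph, cols, keep)
        except Exception:
            pen *= 10.0
    raise RuntimeError("Cox model failed to converge even with heavy penalization")


def build(spec: ModelSpec):
    """Build the neural model for a spec (non-NN designs are handled by the
    training protocol, which fits CPH / late-average compositions per fold)."""
    builders = {
        "mlp_clinical": build_clinical_mlp,
        "early_mlp": build_clinical_mlp,     # identical MLP on the widened input
        "resnet_volume": build_volume_resnet,
        "joint_late": build_joint_late_fusion,
        "jeps": build_jeps,
    }
    if spec.design not in builders:
        raise ValueError(f"design {spec.design!r} is not a buildable network")
    return builders[spec.design](spec)


def reference_parameter_counts() -> dict[str, int]:
    """Parameter totals of the three calibrated reference builds."""
    ref = dict(clinical_width=REFERENCE_CLINICAL_WIDTH,
               volume_shape=REFERENCE_VOLUME_SHAPE)
    return {
        "resnet_volume": count_parameters(build_volume_resnet(ModelSpec("resnet_volume", **ref))),
        "joint_late": count_parameters(build_joint_late_fusion(ModelSpec("joint_late", **ref))),
        "jeps": count_parameters(build_jeps(ModelSpec("jeps", **ref))),
    }
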