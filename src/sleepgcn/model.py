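"""Two-branch spatial-temporal graph network with adversarial training.

Architecture per enabled view (functional connectivity "fc", distance "dc"):
temporal attention -> temporal mixing -> spatial attention -> Chebyshev graph
convolution (attention-modulated) -> temporal convolution.  Branch outputs
are concatenated channel-wise, flattened, and fed to an affine-softmax label
head and (optionally) a gradient-reversed domain head.  The FC branch learns
its adjacency per window from the centre epoch's features; the DC branch uses
the fixed electrode-distance graph.

The ablation ladder of configurations:

========  ==========================================================
variant   components
========  ==========================================================
``a``     DC-view Chebyshev graph convolution only
``b``     + temporal convolution
``c``     + spatial/temporal attention
``d``     + FC view and two-view fusion
``e``     + adversarial domain generalization (the full model)
========  ==========================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .attention import (
    apply_temporal_attention_t,
    spatial_attention_t,
    temporal_attention_t,
)
from .domain import cross_entropy_t, domain_logits_t, label_logits_t
from .features import ChannelMontage, ContextWindow, windows_to_array
from .graphs import (
    build_distance_adjacency,
    fc_adjacency_t,
    graph_loss_t,
    laplacian_minus_identity_t,
    scaled_laplacian,
)
from .stgcn import cheb_graph_conv_t, cheb_polynomials, cheb_polynomials_t, temporal_conv_t

N_STAGES = 5

#: fixed order of per-component RNG streams; constant so that enabling or
#: disabling a component never shifts the initialisation of the others
_RNG_STREAMS = (
    "graph_w",
    "att_fc",
    "att_dc",
    "cheb_fc",
    "cheb_dc",
    "tconv_fc",
    "tconv_dc",
    "label_head",
    "domain_head",
    "shuffle",
    "valsplit",
)


@dataclass
class ModelConfig:
    """Hyperparameters and component switches."""

    d: int = 2                      # context radius; window length Tn = 2d + 1
    K: int = 3                      # Chebyshev order (K-1 polynomial degree)
    channels: int = 10              # graph-conv output channels per view
    k_t: int = 3                    # temporal kernel length (odd)
    fd: int = 6                     # features per node
    beta: float = 0.5               # gradient-reversal strength
    gamma: float = 1e-4             # weight of the graph-learning loss
    lambda_reg: float = 0.001       # sparsity weight inside the graph loss
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    seed: int = 0
    hidden_domain: int = 64
    use_temporal_conv: bool = True
    use_attention: bool = True
    use_fc_view: bool = True
    use_dc_view: bool = True
    use_domain_generalization: bool = True
    class_weights: bool = False
    patience: int = 20
    val_fraction: float = 0.1
    attention_init_scale: float = 1e-2
    distance_sigma: float | None = None
    distance_threshold: float = 0.1
    beta_warmup_epochs: int = 0  # 0 = constant beta; >0 = sigmoid ramp 0 -> beta
    grad_clip: float | None = 5.0  # global gradient-norm ceiling (None = off)
    domain_lr_scale: float = 1.0  # relative Adam step size of the domain head
    domain_label_smoothing: float = 0.1  # keeps the adversarial gradient alive
    domain_head_reset_every: int = 0  # re-init the domain head every k epochs (0 = never)
    weight_decay: float = 0.0  # L2 decay on the trunk (not the heads)
    trunk_activation: str = "relu"  # "relu" or "leaky_relu" (recoverable units)
    adaptive_beta: bool = True  # auto-balance: back off the reversal while the
    # label loss sits at chance, restore it once the label task recovers
    beta_backoff_threshold: float = 1.2   # mean epoch loss_y above this -> halve
    beta_recovery_threshold: float = 0.6  # below this -> restore toward 1

    def __post_init__(self):
        if not (self.use_fc_view or self.use_dc_view):
            raise ValueError("at least one brain view must be enabled")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.k_t % 2 != 1:
            raise ValueError("k_t must be odd")
        if self.d < 0:
            raise ValueError("context radius d must be >= 0")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be nonnegative")

    @property
    def tn(self) -> int:
        return 2 * self.d + 1

    @classmethod
    def variant(cls, name: str, **overrides) -> "ModelConfig":
        """Ablation-ladder presets ``a`` .. ``e``."""
        ladder = {
            "a": dict(use_temporal_conv=False, use_attention=False,
                      use_fc_view=False, use_domain_generalization=False),
            "b": dict(use_attention=False, use_fc_view=False,
                      use_domain_generalization=False),
            "c": dict(use_fc_view=False, use_domain_generalization=False),
            "d": dict(use_domain_generalization=False),
            "e": dict(),
        }
        if name not in ladder:
            raise ValueError(f"unknown variant {name!r}; choose from a-e")
        kwargs = dict(ladder[name])
        kwargs.update(overrides)
        return cls(**kwargs)


class SleepGCN:
    """The assembled model: parameters, forward pass, training and inference."""

    def __init__(self, config: ModelConfig, montage: ChannelMontage, n_domains: int = 1):
        config_n = montage.n_channels
        self.config = config
        self.montage = montage
        self.n_domains = int(n_domains)
        if config.use_domain_generalization and self.n_domains < 2:
            raise ValueError("domain generalization requires R_d >= 2 training subjects")
        self.subjects_: list[str] | None = None
        self.history: list[dict] = []
        self._beta_eff = config.beta  # per-epoch effective GRL strength
        self._beta_scale = 1.0  # adaptive multiplier (auto-balancing)
        self._rngs = self._make_rngs(config.seed)
        self.params: dict[str, ad.Tensor] = {}
        self._init_params(config_n)
        # fixed distance view: adjacency, exact scaled Laplacian, Chebyshev basis
        if config.use_dc_view:
            self.A_dc = build_distance_adjacency(
                montage, sigma=config.distance_sigma, threshold=config.distance_threshold
            )
            self.L_tilde_dc = scaled_laplacian(self.A_dc)
            self._cheb_dc = [ad.Tensor(c) for c in cheb_polynomials(self.L_tilde_dc, config.K)]
        else:
            self.A_dc = None
            self.L_tilde_dc = None
            self._cheb_dc = None

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @staticmethod
    def _make_rngs(seed: int) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(seed).spawn(len(_RNG_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_RNG_STREAMS, children)}

    def _param(self, name: str, array: np.ndarray) -> ad.Tensor:
        t = ad.Tensor(array, requires_grad=True)
        self.params[name] = t
        return t

    def _init_params(self, n: int) -> None:
        cfg = self.config
        fd, tn, C = cfg.fd, cfg.tn, cfg.channels
        scale = cfg.attention_init_scale

        if cfg.use_fc_view:
            self._param("w_graph", self._rngs["graph_w"].normal(0.0, 0.1, size=fd))

        for view in ("fc", "dc"):
            if not getattr(cfg, f"use_{view}_view"):
                continue
            if cfg.use_attention:
                rng = self._rngs[f"att_{view}"]
                u = lambda *shape: rng.uniform(-scale, scale, size=shape)
                for pname, shape in (
                    ("Vq", (tn, tn)), ("bq", (tn, tn)), ("M1", (n,)),
                    ("M2", (fd, n)), ("M3", (fd,)),
                    ("Vp", (n, n)), ("bp", (n, n)), ("Z1", (tn,)),
                    ("Z2", (fd, tn)), ("Z3", (fd,)),
                ):
                    self._param(f"{pname}_{view}", u(*shape))
            rng = self._rngs[f"cheb_{view}"]
            glorot = np.sqrt(2.0 / (fd + C))
            self._param(f"Theta_{view}", rng.normal(0.0, glorot, size=(cfg.K, fd, C)))
            if cfg.use_temporal_conv:
                rng = self._rngs[f"tconv_{view}"]
                g2 = np.sqrt(2.0 / (C * cfg.k_t + C))
                self._param(f"Phi_{view}", rng.normal(0.0, g2, size=(C, C, cfg.k_t)))
                self._param(f"tbias_{view}", np.zeros(C))

        n_views = int(cfg.use_fc_view) + int(cfg.use_dc_view)
        self._feat_dim = n * C * n_views * tn
        rng = self._rngs["label_head"]
        gl = np.sqrt(2.0 / (self._feat_dim + N_STAGES))
        self._param("wy", rng.normal(0.0, gl, size=(self._feat_dim, N_STAGES)))
        self._param("by", np.zeros(N_STAGES))
        if cfg.use_domain_generalization:
            self._init_domain_head()

    def _init_domain_head(self) -> None:
        cfg = self.config
        rng = self._rngs["domain_head"]
        h = cfg.hidden_domain
        gd1 = np.sqrt(2.0 / (self._feat_dim + h))
        gd2 = np.sqrt(2.0 / (h + self.n_domains))
        for name, arr in (
            ("wdh", rng.normal(0.0, gd1, size=(self._feat_dim, h))),
            ("bdh", np.zeros(h)),
            ("wd", rng.normal(0.0, gd2, size=(h, self.n_domains))),
            ("bd", np.zeros(self.n_domains)),
        ):
            if name in self.params:
                self.params[name].data = arr
            else:
                self._param(name, arr)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    # ------------------------------------------------------------------
    # forward
    # ------------------------------------------------------------------
    def _branch(self, Xt: ad.Tensor, view: str, centers: ad.Tensor | None, outputs: dict):
        cfg = self.config
        p = self.params
        if cfg.use_attention:
            Qp = temporal_attention_t(
                Xt, p[f"Vq_{view}"], p[f"bq_{view}"],
                p[f"M1_{view}"], p[f"M2_{view}"], p[f"M3_{view}"],
            )
            Xh = apply_temporal_attention_t(Xt, Qp)
            Pp = spatial_attention_t(
                Xh, p[f"Vp_{view}"], p[f"bp_{view}"],
                p[f"Z1_{view}"], p[f"Z2_{view}"], p[f"Z3_{view}"],
            )
            outputs[f"Q_{view}"] = Qp
            outputs[f"P_{view}"] = Pp
            modulation = Pp
        else:
            Xh = Xt
            n = Xt.shape[1]
            modulation = ad.Tensor(np.ones((n, n)))

        if view == "fc":
            A = fc_adjacency_t(centers, p["w_graph"])
            outputs["A_fc"] = A
            A_sym = ad.mul(ad.add(A, ad.moveaxis(A, -1, -2)), 0.5)
            L_tilde = laplacian_minus_identity_t(A_sym)
            cheb = cheb_polynomials_t(L_tilde, cfg.K)
        else:
            cheb = self._cheb_dc

        act = ad.relu if cfg.trunk_activation == "relu" else ad.leaky_relu
        Xg = cheb_graph_conv_t(Xh, cheb, p[f"Theta_{view}"], modulation, activation=act)
        if cfg.use_temporal_conv:
            Xg = temporal_conv_t(Xg, p[f"Phi_{view}"], p[f"tbias_{view}"], activation=act)
        return Xg

    def forward(self, X: np.ndarray) -> dict:
        """Full forward pass on a batch ``[B, N, Fd, Tn]``; returns tape tensors."""
        cfg = self.config
        if X.ndim != 4:
            raise ValueError("batch must be [B, N, Fd, Tn]")
        if X.shape[1] != self.montage.n_channels:
            raise ValueError("channel count does not match the training montage")
        if X.shape[2] != cfg.fd or X.shape[3] != cfg.tn:
            raise ValueError(
                f"expected [*, {self.montage.n_channels}, {cfg.fd}, {cfg.tn}], got {X.shape}"
            )
        Xt = ad.Tensor(np.asarray(X, dtype=np.float64))
        centers = Xt[:, :, :, cfg.d]  # [B, N, Fd] features of the centre epoch
        outputs: dict = {}
        branches = []
        if cfg.use_fc_view:
            branches.append(self._branch(Xt, "fc", centers, outputs))
        if cfg.use_dc_view:
            branches.append(self._branch(Xt, "dc", centers, outputs))
        fused = branches[0] if len(branches) == 1 else ad.concatenate(branches, axis=-2)
        feats = ad.reshape(fused, (X.shape[0], -1))
        outputs["features"] = feats
        outputs["logits_y"] = label_logits_t(feats, self.params["wy"], self.params["by"])
        if cfg.use_domain_generalization:
            outputs["logits_d"] = domain_logits_t(
                feats, self.params["wdh"], self.params["bdh"],
                self.params["wd"], self.params["bd"], self._beta_eff,
            )
        if cfg.use_fc_view:
            outputs["loss_graph"] = graph_loss_t(centers, outputs["A_fc"], cfg.lambda_reg)
        outputs["centers"] = centers
        return outputs

    def _loss(self, out: dict, y: np.ndarray, dom: np.ndarray | None,
              class_w: np.ndarray | None) -> tuple[ad.Tensor, dict]:
        cfg = self.config
        loss_y = cross_entropy_t(out["logits_y"], y)
        if class_w is not None:
            logp = ad.log_softmax(out["logits_y"], axis=-1)
            w = class_w[y]
            picked = logp[(np.arange(len(y)), y)]
            loss_y = ad.mul(ad.neg(ad.tsum(ad.mul(picked, w))), 1.0 / w.sum())
        total = loss_y
        parts = {"loss_y": float(loss_y.data)}
        if cfg.use_domain_generalization and dom is not None:
            loss_d = cross_entropy_t(out["logits_d"], dom, cfg.domain_label_smoothing)
            total = ad.add(total, loss_d)
            parts["loss_d"] = float(loss_d.data)
        else:
            parts["loss_d"] = 0.0
        if cfg.use_fc_view and cfg.gamma > 0:
            total = ad.add(total, ad.mul(out["loss_graph"], cfg.gamma))
            parts["loss_graph"] = float(out["loss_graph"].data)
        else:
            parts["loss_graph"] = float(out.get("loss_graph").data) if "loss_graph" in out else 0.0
        parts["loss_total"] = float(total.data)
        return total, parts

    # ------------------------------------------------------------------
    # training
    # ------------------------------------------------------------------
    def fit(self, windows: list[ContextWindow], verbose: bool = False) -> "SleepGCN":
        """Mini-batch Adam training on standardized context windows."""
        cfg = self.config
        X, y, subj = windows_to_array(windows)
        self.subjects_ = sorted(set(subj.tolist()))
        if cfg.use_domain_generalization and len(self.subjects_) < 2:
            raise ValueError(
                "domain generalization requires R_d >= 2 subjects in the training set"
            )
        if cfg.use_domain_generalization and len(self.subjects_) != self.n_domains:
            raise ValueError(
                f"model built for {self.n_domains} domains but "
                f"{len(self.subjects_)} subjects supplied"
            )
        sub_index = {s: i for i, s in enumerate(self.subjects_)}
        dom = np.array([sub_index[s] for s in subj], dtype=int)

        class_w = None
        if cfg.class_weights:
            counts = np.bincount(y, minlength=N_STAGES).astype(float)
            inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
            class_w = inv * (counts > 0).sum() / inv.sum() if inv.sum() else None

        n = len(windows)
        val_idx = np.array([], dtype=int)
        train_idx = np.arange(n)
        if cfg.val_fraction > 0 and cfg.patience > 0 and n >= 20:
            perm = self._rngs["valsplit"].permutation(n)
            n_val = max(1, int(round(cfg.val_fraction * n)))
            val_idx, train_idx = perm[:n_val], perm[n_val:]

        domain_names = {"wdh", "bdh", "wd", "bd"}
        main_params = [p for k, p in self.params.items() if k not in domain_names]
        dom_params = [p for k, p in self.params.items() if k in domain_names]
        opt = ad.Adam(main_params, lr=cfg.learning_rate)
        opt_dom = (
            ad.Adam(dom_params, lr=cfg.learning_rate * cfg.domain_lr_scale)
            if dom_params
            else None
        )
        shuffle_rng = self._rngs["shuffle"]
        best_val = np.inf
        best_state = None
        stall = 0
        for epoch in range(cfg.epochs):
            if cfg.beta_warmup_epochs > 0:
                # sigmoid ramp 0 -> beta, the usual stabiliser of adversarial
                # training: the label task settles before the reversal bites
                p = min(1.0, epoch / cfg.beta_warmup_epochs)
                self._beta_eff = cfg.beta * (2.0 / (1.0 + np.exp(-10.0 * p)) - 1.0)
            else:
                self._beta_eff = cfg.beta
            self._beta_eff *= self._beta_scale
            if (
                cfg.use_domain_generalization
                and cfg.domain_head_reset_every > 0
                and epoch > 0
                and epoch % cfg.domain_head_reset_every == 0
            ):
                self._init_domain_head()
                opt_dom = ad.Adam(
                    [self.params[k] for k in ("wdh", "bdh", "wd", "bd")],
                    lr=cfg.learning_rate * cfg.domain_lr_scale,
                )
            order = shuffle_rng.permutation(train_idx)
            sums = {"loss_y": 0.0, "loss_d": 0.0, "loss_graph": 0.0, "loss_total": 0.0}
            nb = 0
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                out = self.forward(X[batch])
                total, parts = self._loss(out, y[batch], dom[batch], class_w)
                opt.zero_grad()
                if opt_dom is not None:
                    opt_dom.zero_grad()
                total.backward()
                if cfg.grad_clip is not None:
                    # clip the feature/label path and the domain head as
                    # separate groups, so an inert (beta = 0) domain head
                    # cannot perturb the main update
                    for group in (main_params, dom_params):
                        sq = sum(
                            float((p.grad**2).sum()) for p in group if p.grad is not None
                        )
                        norm = np.sqrt(sq)
                        if norm > cfg.grad_clip:
                            scale = cfg.grad_clip / norm
                            for p in group:
                                if p.grad is not None:
                                    p.grad = p.grad * scale
                if cfg.weight_decay > 0:
                    for k, p in self.params.items():
                        if k not in domain_names and k not in ("wy", "by"):
                            if p.grad is not None:
                                p.grad = p.grad + cfg.weight_decay * p.data
                opt.step()
                if opt_dom is not None:
                    opt_dom.step()
                for k in sums:
                    sums[k] += parts[k]
                nb += 1
            record = {k: v / max(nb, 1) for k, v in sums.items()}
            record["epoch"] = epoch
            record["beta_eff"] = self._beta_eff
            if cfg.adaptive_beta and cfg.use_domain_generalization and cfg.beta > 0:
                if record["loss_y"] > cfg.beta_backoff_threshold:
                    self._beta_scale = max(self._beta_scale * 0.5, 0.05)
                elif record["loss_y"] < cfg.beta_recovery_threshold:
                    self._beta_scale = min(self._beta_scale * 1.3, 1.0)
            if len(val_idx):
                out = self.forward(X[val_idx])
                val_loss = float(cross_entropy_t(out["logits_y"], y[val_idx]).data)
                record["val_loss_y"] = val_loss
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    best_state = {k: p.data.copy() for k, p in self.params.items()}
                    stall = 0
                else:
                    stall += 1
            self.history.append(record)
            if verbose:
                print(json.dumps(record))
            if len(val_idx) and stall >= cfg.patience:
                break
        if best_state is not None:
            for k, p in self.params.items():
                p.data = best_state[k]
        return self

    # ------------------------------------------------------------------
    # inference
    # ------------------------------------------------------------------
    def predict(self, windows: list[ContextWindow], batch_size: int = 256) -> dict:
        """Labels, probabilities and per-window graph/attention exports.

        Ties in the class posterior break toward the lower stage index
        (``np.argmax`` convention).
        """
        X, _, _ = windows_to_array(windows)
        chunks: dict[str, list[np.ndarray]] = {}
        for start in range(0, len(X), batch_size):
            out = self.forward(X[start : start + batch_size])
            probs = ad.softmax(out["logits_y"], axis=-1).data
            chunk = {"proba": probs}
            for key in ("A_fc", "P_fc", "Q_fc", "P_dc", "Q_dc", "features"):
                if key in out:
                    chunk[key] = out[key].data
            for k, v in chunk.items():
                chunks.setdefault(k, []).append(v)
        result = {k: np.concatenate(v) for k, v in chunks.items()}
        result["labels"] = result["proba"].argmax(axis=1)
        return result

    def extract_features(self, windows: list[ContextWindow], batch_size: int = 256) -> np.ndarray:
        """Frozen fused features (input of the heads), for probing."""
        X, _, _ = windows_to_array(windows)
        feats = []
        for start in range(0, len(X), batch_size):
            feats.append(self.forward(X[start : start + batch_size])["features"].data)
        return np.concatenate(feats)

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Single-archive checkpoint: parameters + config + montage."""
        meta = {
            "config": asdict(self.config),
            "n_domains": self.n_domains,
            "subjects": self.subjects_,
            "montage_names": self.montage.names,
            "history": self.history,
        }
        arrays = {f"param_{k}": p.data for k, p in self.params.items()}
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            montage_coords=self.montage.coords,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "SleepGCN":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
            montage = ChannelMontage(meta["montage_names"], data["montage_coords"])
            model = cls(ModelConfig(**meta["config"]), montage, n_domains=meta["n_domains"])
            model.subjects_ = meta["subjects"]
            model.history = meta["history"]
            for k in list(model.params):
                model.params[k].data = data[f"param_{k}"].copy()
        return model


def build_model(config: ModelConfig, montage: ChannelMontage, n_domains: int = 1) -> SleepGCN:
    """Construct an untrained model (deterministic given ``config.seed``)."""
    return SleepGCN(config, montage, n_domains=n_domains)
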