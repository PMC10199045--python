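"""MAML and the bidirectional Kronecker-factored meta-optimizer (BM-KFO).

Model-agnostic meta-learning seeks initial parameters θ that adapt to a new
task in a few gradient steps: an inner loop takes task-specific steps
``θ' = θ − α ∇L_support(θ)`` and an outer loop descends the query loss at the
adapted parameters, ``θ ← θ − β ∇_θ Σ L_query(θ')``, differentiating through
the inner update (second order) or approximating it (first order).

BM-KFO additionally learns *how* to step.  A meta-optimizer ``U_ξ``
transforms each gradient tensor with a learned Kronecker-factored linear map
(``G ↦ L G R``, one small factor pair per parameter tensor; identity factors
recover plain gradient descent).  Each task is processed in two phases:

* **meta-train** — both parameter sets take a gradient step on the support
  loss: ``θ' = θ − β ∂L/∂θ`` and ``ξ' = ξ − β ∂L/∂ξ``.  The support loss has
  no direct ξ dependence, so the ξ-gradient is defined through a probe
  update ``θ̃ = θ − α U_ξ(∇θ L)`` and ``∂L(θ̃)/∂ξ``;
* **meta-test** — the updated optimizer adapts the updated model:
  ``θ* = θ' − α U_{ξ'}(∇_{θ'} L_support(θ'))``.

The query loss at ``θ*`` is then differentiated with respect to the outer
(θ, ξ) — through both phases by default — and the outer parameters step with
size β (plain SGD, or Adam), averaged over the task batch.

Loss functions are supplied as callables ``loss(theta: dict[str, Tensor],
task) -> scalar Tensor`` so the same machinery runs on segmentation episodes
and on closed-form toy tasks alike.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import prod
from pathlib import Path

import numpy as np

from .autodiff import Tensor, grad, reshape
from .kron_linalg import FactorPair, apply_factored, identity_factors

__all__ = [
    "HyperConfig",
    "MetaState",
    "init_optim_params",
    "meta_update_direction",
    "inner_adapt",
    "maml_outer_step",
    "bmkfo_step",
    "sgd_joint_step",
    "checkpoint_save",
    "checkpoint_load",
    "flat_shape",
]

SCHEMA_VERSION = 1


class NonFiniteLossError(RuntimeError):
    """Raised when a loss or gradient becomes non-finite; names the phase."""


@dataclass(frozen=True)
class HyperConfig:
    """Step sizes and loop structure.

    ``alpha`` is the inner/adaptation step size, ``beta`` the meta step size
    (decayed multiplicatively by ``lr_decay`` every ``lr_decay_every`` outer
    iterations); ``second_order`` selects differentiation through the inner
    phases versus the first-order approximation.
    """

    alpha: float = 0.01
    beta: float = 0.001
    inner_steps: int = 1
    tasks_per_meta_batch: int = 1
    second_order: bool = True
    lr_decay: float = 0.98
    lr_decay_every: int = 1000
    outer_optimizer: str = "sgd"  # "sgd" | "adam"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("step sizes must be nonnegative")
        if self.inner_steps < 1:
            raise ValueError("inner_steps must be >= 1")
        if self.outer_optimizer not in ("sgd", "adam"):
            raise ValueError("outer_optimizer must be 'sgd' or 'adam'")

    def effective_beta(self, iteration: int) -> float:
        return self.beta * self.lr_decay ** (iteration // self.lr_decay_every)


@dataclass
class MetaState:
    """Model parameters θ, optimizer parameters ξ, hyperparameters, counter
    and RNG — everything needed to restore a run bit-compatibly."""

    theta: dict[str, Tensor]
    xi: dict[str, FactorPair]
    hyper: HyperConfig
    iteration: int = 0
    seed: int = 0
    rng: np.random.Generator = None  # type: ignore[assignment]
    adam_m: dict[str, np.ndarray] = field(default_factory=dict)
    adam_v: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)

    def xi_tensors(self) -> dict[str, Tensor]:
        out = {}
        for name, fp in self.xi.items():
            out[f"{name}.L"] = fp.left
            out[f"{name}.R"] = fp.right
        return out


def flat_shape(shape: tuple[int, ...]) -> tuple[int, int]:
    """2-D shape a parameter tensor is flattened to for factoring.

    Convolution kernels ``(out, in*kh*kw)`` stay as-is, biases ``(m,)`` become
    ``(m, 1)``, higher-rank tensors collapse trailing axes.
    """
    if len(shape) == 1:
        return (shape[0], 1)
    if len(shape) == 2:
        return shape
    return (shape[0], prod(shape[1:]))


def init_optim_params(
    theta: dict[str, Tensor], requires_grad: bool = True
) -> dict[str, FactorPair]:
    """One identity FactorPair per parameter tensor (gradient-descent start)."""
    return {
        name: identity_factors(*flat_shape(t.data.shape), requires_grad=requires_grad)
        for name, t in theta.items()
    }


def meta_update_direction(
    grads: dict[str, Tensor], xi: dict[str, FactorPair]
) -> dict[str, Tensor]:
    """U_ξ: transform each gradient tensor with its factored map.

    With identity ξ the output equals the raw gradients.
    """
    out = {}
    for name, g in grads.items():
        if name not in xi:
            raise KeyError(f"no FactorPair configured for parameter tensor {name!r}")
        shape2d = flat_shape(g.data.shape)
        g2 = reshape(g, shape2d)
        out[name] = reshape(apply_factored(g2, xi[name]), g.data.shape)
    return out


def _check_finite(value: Tensor, phase: str, iteration: int | None = None) -> None:
    if not np.isfinite(value.data).all():
        where = f" at iteration {iteration}" if iteration is not None else ""
        raise NonFiniteLossError(f"non-finite loss in {phase} phase{where}: {value.data}")


def _fresh_leaves(theta: dict[str, Tensor]) -> dict[str, Tensor]:
    return {k: Tensor(v.data, requires_grad=True) for k, v in theta.items()}


def inner_adapt(
    theta: dict[str, Tensor],
    loss_fn,
    task,
    alpha: float,
    steps: int,
    create_graph: bool = False,
) -> dict[str, Tensor]:
    """``steps`` plain gradient-descent updates of the task loss from θ.

    θ itself is never mutated; the adapted parameters are a new mapping.
    With ``create_graph=True`` the trajectory stays on the tape so the result
    can be differentiated with respect to the initial θ.
    """
    cur = theta
    names = list(theta)
    for s in range(steps):
        loss = loss_fn(cur, task)
        _check_finite(loss, f"inner_adapt step {s}")
        gs = grad(loss, [cur[k] for k in names], create_graph=create_graph)
        if create_graph:
            cur = {k: cur[k] - Tensor(alpha) * g for k, g in zip(names, gs)}
        else:
            cur = {
                k: Tensor(cur[k].data - alpha * g.data, requires_grad=True)
                for k, g in zip(names, gs)
            }
    return cur


def _outer_apply(
    state: MetaState,
    grads: dict[str, np.ndarray],
    targets: dict[str, Tensor],
) -> None:
    """In-place outer update of leaf tensors with SGD or Adam at the decayed β."""
    h = state.hyper
    beta = h.effective_beta(state.iteration)
    if h.outer_optimizer == "sgd":
        for name, g in grads.items():
            targets[name].data = targets[name].data - beta * g
        return
    t = state.iteration + 1
    for name, g in grads.items():
        m = state.adam_m.get(name, np.zeros_like(g))
        v = state.adam_v.get(name, np.zeros_like(g))
        m = h.adam_beta1 * m + (1 - h.adam_beta1) * g
        v = h.adam_beta2 * v + (1 - h.adam_beta2) * g * g
        state.adam_m[name] = m
        state.adam_v[name] = v
        mhat = m / (1 - h.adam_beta1**t)
        vhat = v / (1 - h.adam_beta2**t)
        targets[name].data = targets[name].data - beta * mhat / (np.sqrt(vhat) + h.adam_eps)


def maml_outer_step(state: MetaState, tasks, support_loss_fn, query_loss_fn) -> MetaState:
    """One MAML outer update over a batch of tasks.

    Second-order by default (gradient through the inner adaptation); the
    first-order approximation treats the adapted parameters as leaves.
    """
    if not tasks:
        raise ValueError("task batch must be non-empty")
    h = state.hyper
    names = list(state.theta)
    total = {k: np.zeros_like(state.theta[k].data) for k in names}
    for task in tasks:
        theta_prime = inner_adapt(
            state.theta, support_loss_fn, task, h.alpha, h.inner_steps,
            create_graph=h.second_order,
        )
        lq = query_loss_fn(theta_prime, task)
        _check_finite(lq, "outer (query)", state.iteration)
        wrt = [state.theta[k] for k in names] if h.second_order else [
            theta_prime[k] for k in names
        ]
        gs = grad(lq, wrt)
        for k, g in zip(names, gs):
            total[k] += g.data
    n = float(len(tasks))
    _outer_apply(state, {k: v / n for k, v in total.items()}, state.theta)
    state.iteration += 1
    return state


def bmkfo_step(
    state: MetaState,
    tasks,
    support_loss_fn,
    query_loss_fn,
    freeze_xi: bool = False,
    trace: dict | None = None,
) -> MetaState:
    """One bidirectional meta-Kronecker-factored outer update over a batch.

    Per task: a meta-train phase steps (θ, ξ) on the support loss (the
    ξ-gradient through the probe update, see the module docstring), a
    meta-test phase produces ``θ* = θ' − α U_{ξ'}(∇L_support(θ'))``, and the
    query loss at θ* is differentiated w.r.t. the outer (θ, ξ).  With
    ``freeze_xi`` the optimizer parameters are held fixed (useful for the
    MAML-equivalence check at identity ξ).  If ``trace`` is a dict it receives
    the last task's phase outputs (theta_prime / theta_star / xi_prime arrays)
    for inspection.
    """
    if not tasks:
        raise ValueError("task batch must be non-empty")
    h = state.hyper
    beta = h.effective_beta(state.iteration)
    sg = h.second_order
    names = list(state.theta)
    xi_t = state.xi_tensors()
    xi_names = list(xi_t)
    total_theta = {k: np.zeros_like(state.theta[k].data) for k in names}
    total_xi = {k: np.zeros_like(xi_t[k].data) for k in xi_names}

    for task in tasks:
        # ---- meta-train phase: step theta and xi on the support loss ----
        ls = support_loss_fn(state.theta, task)
        _check_finite(ls, "meta-train", state.iteration)
        g_theta = grad(ls, [state.theta[k] for k in names], create_graph=sg)
        g_theta = dict(zip(names, g_theta))

        if freeze_xi:
            xi_prime = state.xi
        else:
            probe_dir = meta_update_direction(g_theta, state.xi)
            probe = {k: state.theta[k] - Tensor(h.alpha) * probe_dir[k] for k in names}
            l_probe = support_loss_fn(probe, task)
            _check_finite(l_probe, "meta-train (probe)", state.iteration)
            g_xi = grad(l_probe, [xi_t[k] for k in xi_names], create_graph=sg)
            g_xi = dict(zip(xi_names, g_xi))
            xi_prime = {
                name: FactorPair(
                    left=fp.left - Tensor(beta) * g_xi[f"{name}.L"],
                    right=fp.right - Tensor(beta) * g_xi[f"{name}.R"],
                    shape_tag=fp.shape_tag,
                )
                for name, fp in state.xi.items()
            }

        theta_prime = {k: state.theta[k] - Tensor(beta) * g_theta[k] for k in names}

        # ---- meta-test phase: the updated optimizer adapts the model ----
        ls2 = support_loss_fn(theta_prime, task)
        _check_finite(ls2, "meta-test", state.iteration)
        g2 = grad(ls2, [theta_prime[k] for k in names], create_graph=sg)
        direction = meta_update_direction(dict(zip(names, g2)), xi_prime)
        theta_star = {k: theta_prime[k] - Tensor(h.alpha) * direction[k] for k in names}

        # ---- outer update: query loss at theta_star w.r.t. (theta, xi) ----
        lq = query_loss_fn(theta_star, task)
        _check_finite(lq, "outer (query)", state.iteration)
        if trace is not None:
            trace["theta_prime"] = {k: theta_prime[k].data.copy() for k in names}
            trace["theta_star"] = {k: theta_star[k].data.copy() for k in names}
            trace["xi_prime"] = {
                n: (fp.left.data.copy(), fp.right.data.copy())
                for n, fp in xi_prime.items()
            }
        if sg:
            wrt_theta = [state.theta[k] for k in names]
            wrt_xi = [xi_t[k] for k in xi_names]
        else:
            wrt_theta = [theta_star[k] for k in names]
            wrt_xi = (
                [xi_t[k] for k in xi_names]
                if freeze_xi
                else [
                    (xi_prime[n].left if s == "L" else xi_prime[n].right)
                    for n, s in (k.rsplit(".", 1) for k in xi_names)
                ]
            )
        gs = grad(lq, list(wrt_theta) + list(wrt_xi))
        for k, g in zip(names, gs[: len(names)]):
            total_theta[k] += g.data
        for k, g in zip(xi_names, gs[len(names):]):
            total_xi[k] += g.data

    n = float(len(tasks))
    _outer_apply(state, {k: v / n for k, v in total_theta.items()}, state.theta)
    if not freeze_xi:
        _outer_apply(state, {k: v / n for k, v in total_xi.items()}, xi_t)
    state.iteration += 1
    return state


def sgd_joint_step(state: MetaState, tasks, loss_fn) -> MetaState:
    """Plain (non-meta) SGD on the summed task losses — the no-meta baseline."""
    if not tasks:
        raise ValueError("task batch must be non-empty")
    names = list(state.theta)
    total = {k: np.zeros_like(state.theta[k].data) for k in names}
    for task in tasks:
        loss = loss_fn(state.theta, task)
        _check_finite(loss, "sgd", state.iteration)
        gs = grad(loss, [state.theta[k] for k in names])
        for k, g in zip(names, gs):
            total[k] += g.data
    n = float(len(tasks))
    _outer_apply(state, {k: v / n for k, v in total.items()}, state.theta)
    state.iteration += 1
    return state


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def _arr(a: np.ndarray) -> dict:
    return {"shape": list(a.shape), "data": a.ravel().tolist()}


def _unarr(d: dict) -> np.ndarray:
    return np.asarray(d["data"], dtype=np.float64).reshape(d["shape"])


def checkpoint_save(state: MetaState, path) -> None:
    """Serialize a MetaState to a schema-versioned JSON checkpoint.

    JSON with sorted keys keeps save→load→save byte-identical.
    """
    payload = {
        "schema_version": SCHEMA_VERSION,
        "iteration": state.iteration,
        "seed": state.seed,
        "hyper": {
            k: getattr(state.hyper, k)
            for k in HyperConfig.__dataclass_fields__
        },
        "rng_state": state.rng.bit_generator.state,
        "theta": {k: _arr(v.data) for k, v in state.theta.items()},
        "xi": {
            k: {
                "left": _arr(fp.left.data),
                "right": _arr(fp.right.data),
                "shape_tag": list(fp.shape_tag),
            }
            for k, fp in state.xi.items()
        },
        "adam_m": {k: _arr(v) for k, v in state.adam_m.items()},
        "adam_v": {k: _arr(v) for k, v in state.adam_v.items()},
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def checkpoint_load(path, expected_theta: dict[str, tuple] | None = None) -> MetaState:
    """Restore a MetaState; optionally validate against an expected parameter
    structure (name → shape) and fail loudly on mismatch."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as err:
        raise ValueError(f"cannot read checkpoint {path}: {err}") from err
    ver = payload.get("schema_version")
    if ver != SCHEMA_VERSION:
        raise ValueError(
            f"checkpoint schema version {ver} incompatible with {SCHEMA_VERSION}"
        )
    theta = {k: Tensor(_unarr(v), requires_grad=True) for k, v in payload["theta"].items()}
    if expected_theta is not None:
        got = {k: v.data.shape for k, v in theta.items()}
        want = {k: tuple(s) for k, s in expected_theta.items()}
        if got != want:
            raise ValueError(
                f"checkpoint model structure mismatch: checkpoint has {got}, expected {want}"
            )
    xi = {
        k: FactorPair(
            left=Tensor(_unarr(v["left"]), requires_grad=True),
            right=Tensor(_unarr(v["right"]), requires_grad=True),
            shape_tag=tuple(v["shape_tag"]),
        )
        for k, v in payload["xi"].items()
    }
    hyper = HyperConfig(**payload["hyper"])
    rng = np.random.default_rng(payload["seed"])
    rng.bit_generator.state = payload["rng_state"]
    return MetaState(
        theta=theta,
        xi=xi,
        hyper=hyper,
        iteration=payload["iteration"],
        seed=payload["seed"],
        rng=rng,
        adam_m={k: _unarr(v) for k, v in payload.get("adam_m", {}).items()},
        adam_v={k: _unarr(v) for k, v in payload.get("adam_v", {}).items()},
    )


def metakfo_step(state: MetaState, tasks, support_loss_fn, query_loss_fn) -> MetaState:
    """Non-bidirectional Kronecker-factored meta step: the inner adaptation is
    a single U_ξ-preconditioned update, and the query loss at the adapted
    parameters updates both θ and ξ."""
    if not tasks:
        raise ValueError("task batch must be non-empty")
    h = state.hyper
    names = list(state.theta)
    xi_t = state.xi_tensors()
    xi_names = list(xi_t)
    total_theta = {k: np.zeros_like(state.theta[k].data) for k in names}
    total_xi = {k: np.zeros_like(xi_t[k].data) for k in xi_names}
    for task in tasks:
        ls = support_loss_fn(state.theta, task)
        _check_finite(ls, "inner (support)", state.iteration)
        gs = grad(ls, [state.theta[k] for k in names], create_graph=h.second_order)
        direction = meta_update_direction(dict(zip(names, gs)), state.xi)
        theta_prime = {k: state.theta[k] - Tensor(h.alpha) * direction[k] for k in names}
        lq = query_loss_fn(theta_prime, task)
        _check_finite(lq, "outer (query)", state.iteration)
        if h.second_order:
            wrt = [state.theta[k] for k in names] + [xi_t[k] for k in xi_names]
        else:
            wrt = [theta_prime[k] for k in names] + [xi_t[k] for k in xi_names]
        gall = grad(lq, wrt)
        for k, g in zip(names, gall[: len(names)]):
            total_theta[k] += g.data
        for k, g in zip(xi_names, gall[len(names):]):
            total_xi[k] += g.data
    n = float(len(tasks))
    _outer_apply(state, {k: v / n for k, v in total_theta.items()}, state.theta)
    _outer_apply(state, {k: v / n for k, v in total_xi.items()}, xi_t)
    state.iteration += 1
    return state
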