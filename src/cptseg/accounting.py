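"""Deterministic parameter and FLOP accounting with convention calibration.

Complexity figures reported for deep networks are notoriously
convention-dependent: whether biases and norm affines are counted,
whether a multiply-accumulate (MAC) is one FLOP or two, whether the
attention score/weighting matmuls (which live outside parametrized
layers and are invisible to hook-based profilers) are included, and
what divisor turns raw counts into "M"/"G".  This module makes every
choice explicit in a :class:`ConventionFlags` record, counts exactly
(integer arithmetic over an instantiated model; runtime MAC tracing for
FLOPs), and provides :func:`calibrate_convention`, which recovers the
convention behind a set of printed figures from their inter-row deltas
— deltas depend only on the transformer stack and are therefore immune
to the unreported backbone truncation.
"""

from __future__ import annotations

import contextlib
import gc
import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import engine
from .engine import Tensor
from .networks import NetworkConfig, SegModel, build_model

MIB = float(1 << 20)          # "binary millions"


@dataclass(frozen=True)
class ConventionFlags:
    """Everything that decides how raw counts become printed numbers."""

    count_bias: bool = True
    include_norms: bool = True
    param_scale: float = MIB          # printed M = count / param_scale
    flop_scale: float = 1e9           # printed G = macs / flop_scale
    count_attention_matmuls: bool = False
    count_hadamard: bool = False
    macs_as_flops: bool = True        # False doubles (1 MAC = 2 FLOPs)

    def describe(self) -> dict:
        return asdict(self)


DEFAULT_CONVENTION = ConventionFlags()


@dataclass
class AccountingReport:
    params_millions: float = 0.0
    flops_giga: float = 0.0
    breakdown: list[tuple[str, float, float]] = field(default_factory=list)
    convention: ConventionFlags = DEFAULT_CONVENTION
    raw_params: int = 0
    raw_macs: int = 0

    def rounded(self) -> dict:
        return {
            "params_millions": round(self.params_millions, 2),
            "flops_giga": round(self.flops_giga, 2),
            "breakdown": [(n, round(p, 2), round(f, 2))
                          for n, p, f in self.breakdown],
            "convention": self.convention.describe(),
        }

    def to_json(self) -> str:
        return json.dumps(self.rounded(), indent=2)


# ---------------------------------------------------------------------------
# Raw tallies (convention-free)
# ---------------------------------------------------------------------------

def _component_of(name: str) -> str:
    head = name.split(".", 1)[0]
    return {"encoder": "encoder", "transformer": "transformer",
            "decoder": "decoder", "encoder_norm": "transformer"}.get(head, head)


def parameter_tally(model) -> list[tuple[str, int, bool, bool]]:
    """Per-parameter records ``(component, size, is_bias, is_norm)``."""
    out = []
    for name, p in model.named_parameters():
        is_norm = name.endswith((".gain", ".shift"))
        is_bias = name.endswith(".bias")
        out.append((_component_of(name), p.data.size, is_bias, is_norm))
    return out


def mac_tally(model: SegModel, image_size: int | None = None,
              batch: int = 1, trace: bool = True) -> dict[str, dict[str, int]]:
    """Per-component, per-category MAC counts for one forward pass.

    With ``trace=True`` the forward is shape-only (matmuls/convs skipped);
    MAC counts are identical, runtime is near-zero.
    """
    cfg = model.cfg
    size = image_size or cfg.image_size
    if size != cfg.image_size:
        raise ValueError("image_size must match the model config")
    model.eval()
    dummy = Tensor(np.zeros((batch, cfg.in_channels, size, size), dtype=np.float64))
    result: dict[str, dict[str, int]] = {}
    ctx = engine.tracing() if trace else contextlib.nullcontext()
    with ctx:
        with engine.count_macs() as c:
            tokens, skips = model.hybrid_encode(dummy)
        result["encoder"] = dict(c.by_category)
        with engine.count_macs() as c:
            tokens = model.transform(tokens)
        result["transformer"] = dict(c.by_category)
        with engine.count_macs() as c:
            model.decode_cup(tokens, skips)
        result["decoder"] = dict(c.by_category)
    if batch != 1:
        result = {k: {c_: v // batch for c_, v in d.items()}
                  for k, d in result.items()}
    return result


def _apply_param_convention(tally, conv: ConventionFlags) -> dict[str, int]:
    per = {}
    for comp, size, is_bias, is_norm in tally:
        if is_norm and not conv.include_norms:
            continue
        if is_bias and not conv.count_bias:
            continue
        per[comp] = per.get(comp, 0) + size
    return per

_FLOP_CATEGORIES_ALWAYS = ("linear", "conv", "matmul")


def _apply_flop_convention(macs: dict[str, dict[str, int]],
                           conv: ConventionFlags) -> dict[str, int]:
    cats = list(_FLOP_CATEGORIES_ALWAYS)
    if conv.count_attention_matmuls:
        cats.append("attn_matmul")
    if conv.count_hadamard:
        cats.append("hadamard")
    mult = 1 if conv.macs_as_flops else 2
    return {comp: mult * sum(d.get(c, 0) for c in cats)
            for comp, d in macs.items()}


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def count_parameters(model: SegModel,
                     convention: ConventionFlags = DEFAULT_CONVENTION
                     ) -> AccountingReport:
    """Exact trainable-parameter count under an explicit convention."""
    per = _apply_param_convention(parameter_tally(model), convention)
    total = sum(per.values())
    rep = AccountingReport(convention=convention, raw_params=total)
    rep.params_millions = total / convention.param_scale
    rep.breakdown = [(k, v / convention.param_scale, 0.0)
                     for k, v in sorted(per.items())]
    return rep


def count_flops(model: SegModel, image_size: int | None = None,
                convention: ConventionFlags = DEFAULT_CONVENTION
                ) -> AccountingReport:
    """Forward-pass FLOPs from a traced forward at the given input size."""
    macs = mac_tally(model, image_size)
    per = _apply_flop_convention(macs, convention)
    total = sum(per.values())
    rep = AccountingReport(convention=convention, raw_macs=total)
    rep.flops_giga = total / convention.flop_scale
    rep.breakdown = [(k, 0.0, v / convention.flop_scale)
                     for k, v in sorted(per.items())]
    return rep


def account(cfg: NetworkConfig,
            convention: ConventionFlags = DEFAULT_CONVENTION
            ) -> AccountingReport:
    """Params and FLOPs for a config (zero-init build; values irrelevant)."""
    model = build_model(cfg, init="zeros")
    p = count_parameters(model, convention)
    f = count_flops(model, convention=convention)
    del model
    gc.collect()
    per_p = dict((n, pm) for n, pm, _ in p.breakdown)
    per_f = dict((n, fg) for n, _, fg in f.breakdown)
    rep = AccountingReport(convention=convention,
                           raw_params=p.raw_params, raw_macs=f.raw_macs)
    rep.params_millions = p.params_millions
    rep.flops_giga = f.flops_giga
    rep.breakdown = [(n, per_p.get(n, 0.0), per_f.get(n, 0.0))
                     for n in sorted(set(per_p) | set(per_f))]
    return rep


# ---------------------------------------------------------------------------
# Convention calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    convention: ConventionFlags
    max_rel_error: float
    n_deltas: int
    within_tolerance: bool


def _candidate_conventions():
    for bias, norms, scale, attn, had in itertools.product(
            (True, False), (True, False), (1e6, MIB), (False, True),
            (False, True)):
        yield ConventionFlags(count_bias=bias, include_norms=norms,
                              param_scale=scale,
                              count_attention_matmuls=attn,
                              count_hadamard=had)


def calibrate_convention(rows, tolerance: float = 0.10,
                         min_delta: float = 1.0) -> CalibrationResult:
    """Recover the counting convention behind printed complexity figures.

    ``rows`` is a sequence of ``(NetworkConfig, printed_params_M,
    printed_flops_G_or_None)``; at least three are required.  For every
    candidate convention the model-side *inter-row deltas* are compared
    with the printed deltas (all pairs), and the convention minimizing
    the maximum relative error wins.  Deltas cancel whatever fixed
    backbone the printed totals include, so the calibration is immune to
    the unreported encoder/decoder truncation.

    Pairs whose printed delta is below ``min_delta`` (in printed units)
    are skipped: at two printed decimals such deltas are dominated by
    rounding noise and carry no information about the convention.
    """
    rows = list(rows)
    if len(rows) < 3:
        raise ValueError("calibration needs at least 3 printed rows")
    tallies, mac_tallies, printed_p, printed_f = [], [], [], []
    for cfg, pm, fg in rows:
        model = build_model(cfg, init="zeros")
        tallies.append(parameter_tally(model))
        mac_tallies.append(mac_tally(model) if fg is not None else None)
        printed_p.append(pm)
        printed_f.append(fg)
        del model
        gc.collect()

    best: CalibrationResult | None = None
    for conv in _candidate_conventions():
        totals = [sum(_apply_param_convention(t, conv).values()) / conv.param_scale
                  for t in tallies]
        ftotals = [None if m is None else
                   sum(_apply_flop_convention(m, conv).values()) / conv.flop_scale
                   for m in mac_tallies]
        errs = []
        for i, j in itertools.combinations(range(len(rows)), 2):
            dp = printed_p[j] - printed_p[i]
            if abs(dp) >= min_delta:
                errs.append(abs((totals[j] - totals[i]) - dp) / abs(dp))
            if printed_f[i] is not None and printed_f[j] is not None:
                df = printed_f[j] - printed_f[i]
                if abs(df) >= min_delta:
                    errs.append(abs((ftotals[j] - ftotals[i]) - df) / abs(df))
        if not errs:
            continue
        score = max(errs)
        if best is None or score < best.max_rel_error:
            best = CalibrationResult(conv, score, len(errs),
                                     score <= tolerance)
    if best is None:
        raise ValueError("no comparable deltas among the provided rows")
    if not best.within_tolerance:
        import warnings
        warnings.warn(f"no convention within {tolerance:.0%}; best residual "
                      f"{best.max_rel_error:.1%}", stacklevel=2)
    return best


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def variant_table(configs, convention: ConventionFlags = DEFAULT_CONVENTION
                  ) -> list[dict]:
    """Machine-readable complexity table, one row per config."""
    rows = []
    for cfg in configs:
        rep = account(cfg, convention)
        t = cfg.transformer
        rows.append({
            "variant": cfg.variant,
            "image_size": cfg.image_size,
            "branches": t.parallelism,
            "layers": t.depth,
            "dd_layers": t.dd_layers,
            "mlp_layers": t.mlp_layers,
            "params_M": round(rep.params_millions, 2),
            "flops_G": round(rep.flops_giga, 2),
        })
    return rows


def write_table_csv(rows: list[dict], path) -> None:
    import csv
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
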