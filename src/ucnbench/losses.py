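"""Training objectives: absolute MSE, activity-cliff (AC) and uncommon-node (UCN).

All three are defined per compound pair (i, j) with observed potencies
y_i, y_j, predictions yhat_i, yhat_j and, for UCN, the masked readouts
u_i = xi(phi(M_i(h_i))) over the uncommon atoms of each compound:

    L_MSE = (y_i - yhat_i)^2 + (y_j - yhat_j)^2
    L_AC  = ((y_i - y_j) - (yhat_i - yhat_j))^2
    L_UCN = ((u_i - u_j) - (y_i - y_j))^2

Combined objectives add the auxiliary term with weight lambda:
L_MSE+AC = L_MSE + lambda * L_AC and L_MSE+UCN = L_MSE + lambda * L_UCN
(lambda defaults to 1).  Batch values are means over pairs so lambda keeps its
meaning independent of batch size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

MODES = ("mse", "mse_ac", "mse_ucn")


@dataclass(frozen=True)
class PairLossInput:
    yhat_i: float
    yhat_j: float
    y_i: float
    y_j: float
    u_i: Optional[float] = None  # UCN readout of compound i (uncommon atoms)
    u_j: Optional[float] = None


def mse_pair_loss(inp: PairLossInput) -> float:
    return (inp.y_i - inp.yhat_i) ** 2 + (inp.y_j - inp.yhat_j) ** 2


def ac_loss(inp: PairLossInput) -> float:
    return ((inp.y_i - inp.y_j) - (inp.yhat_i - inp.yhat_j)) ** 2


def ucn_loss(inp: PairLossInput) -> float:
    if inp.u_i is None or inp.u_j is None:
        raise ValueError("UCN loss requires masked readouts u_i and u_j")
    return ((inp.u_i - inp.u_j) - (inp.y_i - inp.y_j)) ** 2


def total_loss(inp: PairLossInput, mode: str, lam: float = 1.0) -> float:
    """Per-pair objective for the requested training mode."""
    if mode == "mse":
        return mse_pair_loss(inp)
    if mode == "mse_ac":
        return mse_pair_loss(inp) + lam * ac_loss(inp)
    if mode == "mse_ucn":
        return mse_pair_loss(inp) + lam * ucn_loss(inp)
    raise ValueError(f"unknown loss mode {mode!r}; expected one of {MODES}")


def batch_total_loss(inputs: Iterable[PairLossInput], mode: str, lam: float = 1.0) -> float:
    """Mean of the per-pair objective over a batch."""
    vals = [total_loss(inp, mode, lam) for inp in inputs]
    if not vals:
        raise ValueError("empty batch")
    return sum(vals) / len(vals)
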