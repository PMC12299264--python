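"""Closed-form computational-complexity accounting for the three nets.

For a single recall of a dimensioned architecture (NI inputs, ND
delays, NH hidden units, NC output classes) the profile counts binary
additions, binary multiplications, activation-function evaluations and
trainable weights:

=======  ===========================  ========================  ============  ===========================
network  additions                    multiplications           activations   weights
=======  ===========================  ========================  ============  ===========================
FIRNN    NI·ND + NI·NH + NH           NI·ND + NI·NH + NH        NH + 1        NH(NI·ND+1) + NC(NH+1)
GRU      3·NH·ND·(NI+ND) + ND         3·NI·NH·(NI+ND·NH)        4·ND·NH + 1   3·NH(NI+NH+1) + NC(NH+1)
LSTM     4·NH·ND·(NI+ND) + ND         4·NI·NH·(NI+ND·NH)        6·ND·NH + 1   4·NH(NI+NH+1) + NC(NH+1)
=======  ===========================  ========================  ============  ===========================

The LSTM multiplication count is the four-gate analogue of the GRU row
(gate prefactor 4 instead of 3); see docs/methods.md for why this form
was adopted.  The weight column equals the runtime scalar count of
``networks.init_params`` for every architecture (tested identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dims import ARCHS, ArchDims

__all__ = ["ComplexityProfile", "complexity_profile", "complexity_table"]

_COLUMNS = ("n_add", "n_mul", "n_act", "n_weights")


@dataclass(frozen=True)
class ComplexityProfile:
    """Operation and parameter counts for one (arch, dims) pair."""

    arch: str
    dims: ArchDims
    n_add: int
    n_mul: int
    n_act: int
    n_weights: int

    def as_dict(self) -> dict:
        return {
            "arch": self.arch,
            "ni": self.dims.ni,
            "nd": self.dims.nd,
            "nh": self.dims.nh,
            "nc": self.dims.nc,
            "n_add": self.n_add,
            "n_mul": self.n_mul,
            "n_act": self.n_act,
            "n_weights": self.n_weights,
        }


def complexity_profile(arch: str, dims: ArchDims) -> ComplexityProfile:
    """Evaluate the closed-form counts for ``arch`` at ``dims``."""
    dims.validate()
    ni, nd, nh, nc = dims.ni, dims.nd, dims.nh, dims.nc
    if arch == "firnn":
        n_add = n_mul = ni * nd + ni * nh + nh
        n_act = nh + 1
        n_weights = nh * (ni * nd + 1) + nc * (nh + 1)
    elif arch == "gru":
        n_add = 3 * nh * nd * (ni + nd) + nd
        n_mul = 3 * ni * nh * (ni + nd * nh)
        n_act = 4 * nd * nh + 1
        n_weights = 3 * nh * (ni + nh + 1) + nc * (nh + 1)
    elif arch == "lstm":
        n_add = 4 * nh * nd * (ni + nd) + nd
        n_mul = 4 * ni * nh * (ni + nd * nh)
        n_act = 6 * nd * nh + 1
        n_weights = 4 * nh * (ni + nh + 1) + nc * (nh + 1)
    else:
        raise ValueError(f"unknown architecture {arch!r}; expected one of {ARCHS}")
    return ComplexityProfile(arch, dims, n_add, n_mul, n_act, n_weights)


def complexity_table(archs, dims_list) -> pd.DataFrame:
    """One profile row per (arch, dims), with per-column minima flagged.

    ``min_<col>`` boolean columns mark which rows attain each column's
    minimum across the table.
    """
    archs = list(archs)
    dims_list = list(dims_list)
    if not archs or not dims_list:
        raise ValueError("archs and dims_list must be nonempty")
    rows = [
        complexity_profile(a, d).as_dict() for a in archs for d in dims_list
    ]
    df = pd.DataFrame(rows)
    for col in _COLUMNS:
        df[f"min_{col}"] = df[col] == df[col].min()
    return df
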