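"""Per-field and per-core quantification: Ki67 sum, CK sum, Ki67/CK ratio.

A core's Ki67 sum and CK sum are the total unmixed signal intensities over
all its fields (six per core in the reference protocol); the Ki67/CK ratio
is their quotient, a proliferation statistic normalised by tumour content
that may exceed 1.  Supra-threshold pixel counts are carried along as
diagnostics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateCoreError, InvalidParameterError
from .unmixing import AbundanceMaps

logger = logging.getLogger(__name__)

__all__ = [
    "FieldQuant",
    "CoreQuant",
    "quantify_field",
    "aggregate_core",
    "compute_ratio",
    "noise_threshold",
]


def noise_threshold(library, noise_sd: float, n_sigma: float = 3.0) -> float:
    """Abundance threshold suppressing noise-floor pixels, by error propagation.

    Per-band Gaussian noise of standard deviation ``noise_sd`` propagates
    through the least-squares unmixing into per-component abundance noise of
    standard deviation ``noise_sd * ||row_j(pinv E)||``; summing rectified
    noise over many background pixels biases signal sums upward.  Cutting at
    ``n_sigma`` (default 3) times the worst component's abundance noise
    removes that bias while leaving real staining (orders of magnitude
    brighter) untouched.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    pinv = np.linalg.pinv(library.as_matrix)
    return float(n_sigma * noise_sd * np.linalg.norm(pinv, axis=1).max())


@dataclass(frozen=True)
class FieldQuant:
    """Signal totals and supra-threshold pixel counts for one view field."""

    ki67_signal: float
    ck_signal: float
    n_pixels_ki67: int
    n_pixels_ck: int


@dataclass(frozen=True)
class CoreQuant:
    """Aggregated quantification for one TMA core."""

    ki67_sum: float
    ck_sum: float
    ratio: float
    n_fields: int


def compute_ratio(ki67_sum: float, ck_sum: float) -> float:
    """Ki67 sum divided by CK sum: the fraction of tumour signal that is
    proliferating.  Values above 1 are legitimate (strongly proliferative,
    CK-sparse cores); a zero CK sum makes the core degenerate."""
    if ki67_sum < 0:
        raise InvalidParameterError("ki67_sum must be non-negative")
    if ck_sum <= 0:
        raise DegenerateCoreError(f"ck_sum = {ck_sum:g}; ratio undefined, core excluded")
    return ki67_sum / ck_sum


def quantify_field(maps: AbundanceMaps, threshold: float = 0.0) -> FieldQuant:
    """Sum Ki67 and CK abundances over pixels strictly above ``threshold``.

    With the default threshold 0 every pixel the unmixer assigned signal to
    contributes; a small positive threshold suppresses noise floor pixels
    in real data.
    """
    if threshold < 0:
        raise InvalidParameterError("threshold must be non-negative")
    ki67_mask = maps.ki67_map > threshold
    ck_mask = maps.ck_map > threshold
    return FieldQuant(
        ki67_signal=float(maps.ki67_map[ki67_mask].sum()),
        ck_signal=float(maps.ck_map[ck_mask].sum()),
        n_pixels_ki67=int(np.count_nonzero(ki67_mask)),
        n_pixels_ck=int(np.count_nonzero(ck_mask)),
    )


def aggregate_core(fields: Sequence[FieldQuant]) -> CoreQuant:
    """Sum field quantifications into one core and attach the ratio.

    Six fields per core is the reference protocol; other counts are
    accepted with a warning so partial cores remain usable.
    """
    if len(fields) == 0:
        raise InvalidParameterError("aggregate_core needs at least one field")
    if len(fields) != 6:
        warnings.warn(
            f"core aggregated from {len(fields)} fields (protocol uses 6)",
            stacklevel=2,
        )
    ki67_sum = float(sum(f.ki67_signal for f in fields))
    ck_sum = float(sum(f.ck_signal for f in fields))
    return CoreQuant(
        ki67_sum=ki67_sum,
        ck_sum=ck_sum,
        ratio=compute_ratio(ki67_sum, ck_sum),
        n_fields=len(fields),
    )
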