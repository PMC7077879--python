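"""Generator for replicated inbred-line life span panels.

Emulates a DGRP-style design: ``n_lines`` inbred lines, two sexes,
several thermal environments, ``vials_per_line_per_temp`` replicate
vials per line and environment with a fixed number of flies of each sex
per vial (defaults: 186 lines x 24 vials x 3 flies/sex/vial = 72
flies/sex/line/temperature).  Each fly's life span is a sum of draws
from the generative counterpart of the cross-classified mixed model:

    Y = mu(sex, temp) + L + LxS + LxT + LxSxT + vial + eps

where the residual standard deviation is itself line-specific on the
log scale (a log-normal line effect on sigma_eps), so that
micro-environmental variance is heritable.  Life spans are truncated
below at a floor of 1 day, and whole line x temperature cells can be
dropped to mimic lines that fail to produce flies at extreme
temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["PanelDesign", "LogSdModel", "TrueComponents", "simulate_lifespan_panel"]


@dataclass(frozen=True)
class PanelDesign:
    """Layout of the replicated panel."""

    n_lines: int = 186
    temperatures: tuple = (18, 25, 28)
    sexes: tuple = ("F", "M")
    vials_per_line_per_temp: int = 24
    flies_per_sex_per_vial: int = 3
    #: fraction of lines dropped entirely at each temperature (poor
    #: viability); defaults mirror 3/186 lines lost at 18C, 9/186 at 28C
    missing_line_fraction_per_temp: Mapping = field(
        default_factory=lambda: {18: 3 / 186, 25: 0.0, 28: 9 / 186}
    )

    def __post_init__(self):
        if min(self.n_lines, self.vials_per_line_per_temp, self.flies_per_sex_per_vial) < 1:
            raise ValueError("all design counts must be >= 1")
        if len(self.sexes) != 2:
            raise ValueError("exactly two sex labels are required")
        for t, f in dict(self.missing_line_fraction_per_temp).items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"missing fraction for {t} outside [0, 1]")

    @property
    def flies_per_sex_per_line_per_temp(self) -> int:
        return self.vials_per_line_per_temp * self.flies_per_sex_per_vial


@dataclass(frozen=True)
class LogSdModel:
    """Line-structured variation of the log residual standard deviation.

    The fly-level residual SD within a (line, sex, temperature) context
    is ``exp(log(sigma_eps) + lam_L + lam_LS + lam_LT)`` with the
    lambdas drawn from centred normals with the SDs below.  Defaults
    follow the observed scale of heritable micro-environmental variance
    in such panels (between-line SD of ln sigma_eps around 0.23, its
    sex interaction around 0.11).
    """

    sd_line: float = 0.23
    sd_line_sex: float = 0.11
    sd_line_temp: float = 0.15

    def __post_init__(self):
        if min(self.sd_line, self.sd_line_sex, self.sd_line_temp) < 0:
            raise ValueError("log-SD model SDs must be non-negative")


_DEFAULT_MEANS = {
    ("F", 18): 77.86, ("M", 18): 84.97,
    ("F", 25): 41.60, ("M", 25): 44.17,
    ("F", 28): 27.15, ("M", 28): 26.77,
}


@dataclass(frozen=True)
class TrueComponents:
    """Generative parameters: context means and component SDs (days)."""

    means: Mapping = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    sigma_line: float = 8.0
    sigma_line_sex: float = 4.0
    sigma_line_temp: float = 7.0
    sigma_line_sex_temp: float = 4.0
    sigma_vial: float = 3.0
    sigma_eps: float = 12.0
    logsd_model: LogSdModel = field(default_factory=LogSdModel)
    floor: float = 1.0

    def __post_init__(self):
        sds = (
            self.sigma_line, self.sigma_line_sex, self.sigma_line_temp,
            self.sigma_line_sex_temp, self.sigma_vial, self.sigma_eps,
        )
        if min(sds) < 0:
            raise ValueError("component SDs must be non-negative")
        if self.floor < 0:
            raise ValueError("life span floor must be non-negative")


def simulate_lifespan_panel(
    design: PanelDesign, components: TrueComponents, seed: int
) -> pd.DataFrame:
    """Simulate one replicated panel; identical seeds give identical tables.

    Returns a long-format table with one row per fly and columns
    ``line``, ``sex``, ``temperature``, ``vial``, ``lifespan_days``.
    """
    rng = np.random.default_rng(seed)
    c = components
    n_l = design.n_lines
    temps = list(design.temperatures)
    sexes = list(design.sexes)
    n_t, n_s = len(temps), len(sexes)
    n_v = design.vials_per_line_per_temp
    n_f = design.flies_per_sex_per_vial

    for s in sexes:
        for t in temps:
            if (s, t) not in c.means:
                raise ValueError(f"no grand mean provided for context ({s}, {t})")

    # random effects, indexed [line], [line, sex], [line, temp], ...
    a_l = rng.normal(0.0, c.sigma_line, n_l)
    b_ls = rng.normal(0.0, c.sigma_line_sex, (n_l, n_s))
    g_lt = rng.normal(0.0, c.sigma_line_temp, (n_l, n_t))
    d_lst = rng.normal(0.0, c.sigma_line_sex_temp, (n_l, n_s, n_t))
    v_ltv = rng.normal(0.0, c.sigma_vial, (n_l, n_t, n_v))
    lm = c.logsd_model
    lam_l = rng.normal(0.0, lm.sd_line, n_l)
    lam_ls = rng.normal(0.0, lm.sd_line_sex, (n_l, n_s))
    lam_lt = rng.normal(0.0, lm.sd_line_temp, (n_l, n_t))

    # whole line x temperature cells dropped for poor viability
    missing = np.zeros((n_l, n_t), dtype=bool)
    fracs = dict(design.missing_line_fraction_per_temp)
    for j, t in enumerate(temps):
        n_drop = int(math.ceil(fracs.get(t, 0.0) * n_l)) if fracs.get(t, 0.0) > 0 else 0
        if n_drop:
            missing[rng.choice(n_l, size=n_drop, replace=False), j] = True

    line_ids = np.array([f"L{i + 1:03d}" for i in range(n_l)])
    frames = []
    for j, t in enumerate(temps):
        keep = np.flatnonzero(~missing[:, j])
        for k, s in enumerate(sexes):
            mu = c.means[(s, t)]
            base = (
                mu
                + a_l[keep]
                + b_ls[keep, k]
                + g_lt[keep, j]
                + d_lst[keep, k, j]
            )  # (L,)
            if c.sigma_eps > 0:
                sd_fly = np.exp(
                    np.log(c.sigma_eps) + lam_l[keep] + lam_ls[keep, k] + lam_lt[keep, j]
                )
            else:
                sd_fly = np.zeros(len(keep))
            # (L, vials, flies)
            y = (
                base[:, None, None]
                + v_ltv[keep, j, :][:, :, None]
                + rng.normal(0.0, 1.0, (len(keep), n_v, n_f)) * sd_fly[:, None, None]
            )
            np.maximum(y, c.floor, out=y)
            frames.append(
                pd.DataFrame(
                    {
                        "line": np.repeat(line_ids[keep], n_v * n_f),
                        "sex": s,
                        "temperature": t,
                        "vial": np.tile(np.repeat(np.arange(1, n_v + 1), n_f), len(keep)),
                        "lifespan_days": y.ravel(),
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["line", "temperature", "vial", "sex"], kind="stable"
    ).reset_index(drop=True)
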