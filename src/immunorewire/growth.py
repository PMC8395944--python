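"""Tumor volume computation and permutation comparison of growth curves.

Volume follows V = (W^2 x L) / 2 with width/length swap-normalized so that
W <= L.  Group curves are compared by permuting mouse-to-group assignments
(mice, not observations, are the exchangeable unit) with the statistic
``mean over shared days of |mean volume(control) - mean volume(treated)|``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurveSet",
    "PermTestResult",
    "tumor_volume",
    "compare_growth_curves",
    "endpoint_reduction",
]

GROUPS = ("control", "treated")


def tumor_volume(width_mm: float, length_mm: float) -> float:
    """V = (W^2 x L) / 2 in mm^3; inputs swap-normalized so W <= L."""
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("width and length must be positive")
    w, l = sorted((float(width_mm), float(length_mm)))
    return (w * w * l) / 2.0


@dataclass
class GrowthCurveSet:
    """Longitudinal tumor measurements; one row per (mouse, day)."""

    frame: pd.DataFrame  # mouse_id, group, day, width_mm, length_mm, volume_mm3

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GrowthCurveSet":
        required = {"mouse_id", "group", "day", "width_mm", "length_mm"}
        if not required.issubset(frame.columns):
            raise ValueError(f"growth table needs columns {sorted(required)}")
        frame = frame.copy()
        bad_groups = set(frame["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
        swapped = frame["width_mm"] > frame["length_mm"]
        if swapped.any():
            warnings.warn(
                f"{int(swapped.sum())} record(s) had width > length; swap-normalized",
                stacklevel=2,
            )
            w = frame.loc[swapped, "width_mm"].copy()
            frame.loc[swapped, "width_mm"] = frame.loc[swapped, "length_mm"]
            frame.loc[swapped, "length_mm"] = w
        if (frame["width_mm"] <= 0).any() or (frame["length_mm"] <= 0).any():
            raise ValueError("nonpositive tumor dimension")
        frame["volume_mm3"] = frame["width_mm"] ** 2 * frame["length_mm"] / 2.0
        for mouse, sub in frame.groupby("mouse_id"):
            days = sub["day"].to_numpy()
            if (np.diff(days) <= 0).any():
                raise ValueError(f"days for mouse {mouse!r} are not strictly increasing")
        return cls(frame=frame)

    @classmethod
    def read_tsv(cls, path) -> "GrowthCurveSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def volume_matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(volumes mice x shared days, group labels per mouse, mouse ids, days)."""
        day_sets = [set(sub["day"]) for _, sub in self.frame.groupby("mouse_id")]
        shared = sorted(set.intersection(*day_sets))
        if not shared:
            raise ValueError("no measurement day shared by all mice")
        sub = self.frame[self.frame["day"].isin(shared)]
        pivot = sub.pivot_table(index="mouse_id", columns="day", values="volume_mm3")
        groups = (
            self.frame.drop_duplicates("mouse_id").set_index("mouse_id")["group"]
        )
        mice = pivot.index.to_numpy()
        return (
            pivot.to_numpy(),
            groups.loc[pivot.index].to_numpy(),
            mice,
            np.asarray(shared),
        )


@dataclass
class PermTestResult:
    observed: float
    n_perm: int
    p: float
    seed: int | None
    exhaustive: bool = False


def _curve_stat(volumes: np.ndarray, is_control: np.ndarray) -> float:
    """Mean over days of |mean control volume - mean treated volume|."""
    diff = volumes[is_control].mean(axis=0) - volumes[~is_control].mean(axis=0)
    return float(np.abs(diff).mean())


def compare_growth_curves(
    g: GrowthCurveSet,
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> PermTestResult:
    """Permutation test on group growth curves, permuting mice between groups.

    p = (1 + #{permuted stat >= observed}) / (1 + n_perm), never exactly 0.
    When the number of distinct group assignments is at most ``n_perm`` (or
    ``exhaustive=True``), all assignments are enumerated instead and
    p = #{stat >= observed} / #assignments over the full permutation set.
    """
    volumes, groups, _, _ = g.volume_matrix()
    is_control = groups == "control"
    n_ctrl = int(is_control.sum())
    n_total = volumes.shape[0]
    if n_ctrl < 2 or n_total - n_ctrl < 2:
        raise ValueError("need at least 2 mice per group")
    observed = _curve_stat(volumes, is_control)

    n_exhaustive = comb(n_total, n_ctrl)
    if exhaustive is None:
        exhaustive = n_exhaustive <= n_perm
    if exhaustive:
        count = 0
        for combo in combinations(range(n_total), n_ctrl):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(combo)] = True
            if _curve_stat(volumes, mask) >= observed - 1e-12:
                count += 1
        return PermTestResult(
            observed=observed,
            n_perm=n_exhaustive,
            p=count / n_exhaustive,
            seed=None,
            exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        mask = np.zeros(n_total, dtype=bool)
        mask[perm[:n_ctrl]] = True
        if _curve_stat(volumes, mask) >= observed - 1e-12:
            count += 1
    return PermTestResult(
        observed=observed,
        n_perm=n_perm,
        p=(1 + count) / (1 + n_perm),
        seed=seed,
        exhaustive=False,
    )


def endpoint_reduction(g: GrowthCurveSet) -> float:
    """1 - mean(treated final volumes) / mean(control final volumes) at the
    final shared measurement day."""
    volumes, groups, _, _ = g.volume_matrix()
    is_control = groups == "control"
    ctrl_mean = volumes[is_control, -1].mean()
    if ctrl_mean == 0:
        raise ValueError("control endpoint mean volume is zero")
    return float(1.0 - volumes[~is_control, -1].mean() / ctrl_mean)
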