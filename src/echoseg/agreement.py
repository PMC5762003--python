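"""Multi-rater agreement statistics.

Computer-to-observer (COD) and inter-observer (IOD) pairwise metric
tables, the extended Williams' index with a jackknife 95% CI, paired
t-tests on per-image means, and per-stage area agreement.

Williams' index, per image with n observers:

    WI_i = [ (1/n) * sum_j 1/m_0j ] / [ (2/(n(n-1))) * sum_{j<j'} 1/m_jj' ]

where m_0j are the computer-vs-observer (COD) disagreement values and
m_jj' the observer-vs-observer (IOD) values.  The overall index is the
mean over images; the 95% CI comes from a leave-one-image-out jackknife
with a normal approximation.  An index whose CI contains 1.0 means the
computer agrees with the observers as well as they agree with each other.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_NAMES, evaluate_pair

__all__ = [
    "AgreementTable",
    "WilliamsResult",
    "AreaRecord",
    "pairwise_table",
    "williams_index",
    "paired_metric_test",
    "area_cm2",
    "area_agreement",
]

logger = logging.getLogger(__name__)

ZERO_FLOOR = 1e-9


@dataclass
class AgreementTable:
    """Rows of (image_id, rater_a, rater_b, seven metrics); mode COD or IOD."""

    rows: pd.DataFrame
    mode: str  # "COD" | "IOD"

    def per_image_means(self, metric):
        return self.rows.groupby("image_id", sort=True)[metric].mean()


@dataclass(frozen=True)
class WilliamsResult:
    metric_name: str
    wi: float
    ci_low: float
    ci_high: float
    n_images: int


@dataclass
class AreaRecord:
    image_id: str
    stage: str
    area_auto: float  # cm^2
    area_operators: list  # cm^2 each


def _grid(m):
    return m.grid if hasattr(m, "grid") else np.asarray(m).astype(bool)


def pairwise_table(auto_masks, operator_masks, mode="COD", spacings=None):
    """Build a pairwise agreement table.

    Parameters
    ----------
    auto_masks : dict image_id -> mask
        Required for COD; ignored for IOD (may be None).
    operator_masks : dict image_id -> list of masks
    mode : "COD" | "IOD"
        COD pairs the automatic mask with each operator; IOD pairs
        distinct operators (both give 3 rows per image with 3 operators).
    spacings : dict image_id -> mm/pixel, optional (default 1.0)
    """
    if mode not in ("COD", "IOD"):
        raise ValueError(f"mode must be COD or IOD, got {mode!r}")
    rows = []
    for image_id in sorted(operator_masks):
        ops = operator_masks[image_id]
        if ops is None or len(ops) == 0:
            raise ValueError(f"missing operator mask for image {image_id!r}")
        sp = 1.0 if spacings is None else spacings[image_id]
        if mode == "COD":
            if auto_masks is None or image_id not in auto_masks:
                raise ValueError(f"missing automatic mask for image {image_id!r}")
            auto = auto_masks[image_id]
            for j, op in enumerate(ops):
                pm = evaluate_pair(_grid(auto), _grid(op), spacing=sp)
                rows.append(dict(image_id=image_id, rater_a="auto", rater_b=f"op{j}", **pm.as_dict()))
        else:
            for j, jp in itertools.combinations(range(len(ops)), 2):
                pm = evaluate_pair(_grid(ops[j]), _grid(ops[jp]), spacing=sp)
                rows.append(dict(image_id=image_id, rater_a=f"op{j}", rater_b=f"op{jp}", **pm.as_dict()))
    return AgreementTable(pd.DataFrame(rows), mode)


def _per_image_wi(cod_vals, iod_vals):
    """Williams' index for one image from its COD and IOD value lists."""
    cod = np.maximum(np.asarray(cod_vals, dtype=float), ZERO_FLOOR)
    iod = np.maximum(np.asarray(iod_vals, dtype=float), ZERO_FLOOR)
    # n observers: len(cod) = n, len(iod) = n(n-1)/2
    num = np.mean(1.0 / cod)
    den = np.mean(1.0 / iod)
    return num / den


def williams_index(cod: AgreementTable, iod: AgreementTable, metric: str) -> WilliamsResult:
    """Extended Williams' index for one metric, with jackknife 95% CI.

    Zero metric values (perfect-agreement rows) are floored at 1e-9 before
    inversion (logged).  Raises if the tables cover different image sets
    or fewer than two observers are present.
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}")
    cod_g = {k: v[metric].to_numpy() for k, v in cod.rows.groupby("image_id")}
    iod_g = {k: v[metric].to_numpy() for k, v in iod.rows.groupby("image_id")}
    if set(cod_g) != set(iod_g):
        raise ValueError("COD and IOD tables cover different image sets")
    n_obs = len(next(iter(cod_g.values())))
    if n_obs < 2:
        raise ValueError("Williams' index needs >= 2 observers")
    n_zero = int(sum((v <= 0).sum() for v in cod_g.values())) + int(
        sum((v <= 0).sum() for v in iod_g.values())
    )
    if n_zero:
        logger.info("williams_index(%s): floored %d zero values at %g", metric, n_zero, ZERO_FLOOR)

    ids = sorted(cod_g)
    wi_per_image = np.array([_per_image_wi(cod_g[i], iod_g[i]) for i in ids])
    wi = float(wi_per_image.mean())
    n = len(ids)
    if n > 1:
        jack = np.array([np.delete(wi_per_image, i).mean() for i in range(n)])
        se = np.sqrt((n - 1) / n * np.sum((jack - jack.mean()) ** 2))
    else:
        se = 0.0
    return WilliamsResult(metric, wi, wi - 1.96 * se, wi + 1.96 * se, n)


def paired_metric_test(table_a: AgreementTable, table_b: AgreementTable, metric: str):
    """Two-sided paired t-test on per-image means (mean over operator rows).

    Returns ``(t, p)``.  Identical tables (zero-variance differences) are
    reported as ``t=0, p=1`` by documented convention.
    """
    a = table_a.per_image_means(metric)
    b = table_b.per_image_means(metric)
    if not a.index.equals(b.index):
        raise ValueError("tables cover different image sets")
    if len(a) < 2:
        raise ValueError("paired t-test needs >= 2 images")
    diff = a.to_numpy() - b.to_numpy()
    if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0.0):
        logger.info("paired_metric_test(%s): zero-variance identical tables; t=0, p=1", metric)
        return 0.0, 1.0
    t, p = stats.ttest_rel(a.to_numpy(), b.to_numpy())
    return float(t), float(p)


def area_cm2(m, spacing=None):
    """Foreground area: pixel count x spacing^2, converted from mm^2 to cm^2."""
    grid = _grid(m)
    sp = getattr(m, "spacing", None) if spacing is None else spacing
    if sp is None:
        sp = 1.0
    return float(grid.sum()) * sp * sp / 100.0


def area_agreement(records):
    """Per-stage area agreement table.

    For each stage: COD = |area_auto - area_op| averaged over operators per
    image then over images (mean +- SD over images); IOD likewise over the
    pairwise |operator differences|; WI with 95% CI via
    :func:`williams_index` on the absolute-difference values.

    Returns a DataFrame with one row per stage that has >= 1 image; stages
    with no images are omitted with a warning.
    """
    by_stage = {}
    for rec in records:
        by_stage.setdefault(rec.stage, []).append(rec)
    out = []
    for stage in ("contraction", "valsalva", "rest"):
        recs = by_stage.pop(stage, None)
        if recs is None:
            logger.warning("area_agreement: no images for stage %r; omitted", stage)
            continue
        cod_rows, iod_rows = [], []
        cod_per_img, iod_per_img = [], []
        for rec in recs:
            cvals = [abs(rec.area_auto - a) for a in rec.area_operators]
            ivals = [abs(a - b) for a, b in itertools.combinations(rec.area_operators, 2)]
            cod_per_img.append(np.mean(cvals))
            iod_per_img.append(np.mean(ivals))
            for j, v in enumerate(cvals):
                cod_rows.append(dict(image_id=rec.image_id, rater_a="auto", rater_b=f"op{j}", dice=v))
            for j, v in enumerate(ivals):
                iod_rows.append(dict(image_id=rec.image_id, rater_a=f"pair{j}", rater_b="", dice=v))
        cod_t = AgreementTable(pd.DataFrame(cod_rows), "COD")
        iod_t = AgreementTable(pd.DataFrame(iod_rows), "IOD")
        wi = williams_index(cod_t, iod_t, "dice")  # column reused as value holder
        out.append(
            dict(
                stage=stage,
                n_images=len(recs),
                cod_mean=float(np.mean(cod_per_img)),
                cod_sd=float(np.std(cod_per_img, ddof=1)) if len(recs) > 1 else 0.0,
                iod_mean=float(np.mean(iod_per_img)),
                iod_sd=float(np.std(iod_per_img, ddof=1)) if len(recs) > 1 else 0.0,
                wi=wi.wi,
                ci_low=wi.ci_low,
                ci_high=wi.ci_high,
            )
        )
    for stage in by_stage:
        logger.warning("area_agreement: unknown stage %r ignored", stage)
    return pd.DataFrame(out)
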