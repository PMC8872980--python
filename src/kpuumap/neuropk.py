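"""Neuropharmacokinetic core: unbound BBB transport and intrabrain
distribution.

Quantities and relations
------------------------
* ``V_u,brain`` (mL g⁻¹): unbound volume of distribution, from the
  brain-slice assay either via the buffer-film-corrected amount form
  ``(A − V_i·C_buf) / (C_buf·(1 − V_i))`` with the inulin-calibrated film
  volume ``V_i = 0.094 mL g⁻¹``, or directly as ``C_tot,slice / C_buf``
  when the adherent buffer layer is removed before measurement.
* ``K_p`` (dimensionless): total brain-to-plasma ratio.
* ``K_p,uu`` (dimensionless): unbound brain-to-plasma ratio.  The
  combinatory-mapping form is ``K_p / (V_u · f_u,plasma)``; the imaging
  (ratio) form is ``CF · C_tot,in vivo / C_tot,slice`` with the correction
  factor ``CF = C_u,buffer / C_u,plasma`` (1 when the incubation buffer
  matches the unbound plasma level).  The two forms agree identically for
  consistent inputs.
* ``C_u,ISF`` (ng mL⁻¹): unbound interstitial-fluid concentration,
  ``C_tot / V_u``.

Interpretation: ``K_p,uu < 1`` net efflux, ``≈ 1`` passive equilibration,
``> 1`` active uptake.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataValidationError

#: Adherent buffer-film volume of an incubated brain slice (mL g⁻¹),
#: measured with a [14C]inulin marker.
V_I_DEFAULT = 0.094

TRANSPORT_CLASSES = ("efflux", "passive", "uptake", "indeterminate")


def v_u_brain_from_amount(a_brain_slice: float, c_u_buffer: float,
                          v_i: float = V_I_DEFAULT) -> float:
    """Unbound volume of distribution from the slice amount (ng g⁻¹),
    correcting for the adherent buffer film of volume ``v_i``.

    A negative result (slice content below the buffer-film content) is
    returned as-is for the caller to flag.
    """
    if c_u_buffer <= 0:
        raise DataValidationError("buffer concentration must be > 0")
    if not (0 <= v_i < 1):
        raise DataValidationError("v_i must lie in [0, 1)")
    return (a_brain_slice - v_i * c_u_buffer) / (c_u_buffer * (1.0 - v_i))


def v_u_brain_from_conc(c_tot_slice: float, c_u_buffer: float) -> float:
    """Unbound volume of distribution as C_tot,slice / C_u,buffer — the
    film-free form used when slice preparation removes the buffer layer."""
    if c_u_buffer <= 0:
        raise DataValidationError("buffer concentration must be > 0")
    return c_tot_slice / c_u_buffer


def kp_total(c_tot_brain: float, c_tot_plasma: float) -> float:
    """Total brain-to-plasma partition coefficient."""
    if c_tot_plasma <= 0:
        raise DataValidationError("plasma concentration must be > 0")
    return c_tot_brain / c_tot_plasma


def kpuu_cma(k_p: float, v_u: float, f_u_plasma: float) -> float:
    """Unbound partition coefficient by the combinatory mapping approach:
    K_p / (V_u · f_u,plasma)."""
    if v_u <= 0:
        raise DataValidationError("V_u must be > 0")
    if not (0 < f_u_plasma <= 1):
        raise DataValidationError("f_u_plasma must be in (0, 1]")
    return k_p / (v_u * f_u_plasma)


def correction_factor(c_u_buffer: float, c_u_plasma: float) -> float:
    """CF = C_u,buffer / C_u,plasma, applied when the brain-slice buffer
    level differs from the unbound plasma level."""
    if c_u_buffer <= 0 or c_u_plasma <= 0:
        raise DataValidationError("unbound concentrations must be > 0")
    return c_u_buffer / c_u_plasma


def kpuu_ratio(c_tot_invivo: float, c_tot_slice: float,
               cf: float = 1.0) -> float:
    """Imaging form of the unbound partition coefficient:
    CF · C_tot,in vivo / C_tot,slice."""
    if c_tot_slice <= 0:
        raise DataValidationError("slice concentration must be > 0")
    if cf <= 0:
        raise DataValidationError("correction factor must be > 0")
    return cf * c_tot_invivo / c_tot_slice


def unbound_isf_conc(c_tot_invivo: float, v_u: float) -> float:
    """Unbound interstitial-fluid concentration C_tot / V_u (ng mL⁻¹)."""
    if v_u <= 0:
        raise DataValidationError("V_u must be > 0")
    return c_tot_invivo / v_u


def classify_transport(k_p_uu: float,
                       ci: tuple[float, float] | None = None,
                       tolerance: float = 0.1) -> str:
    """Classify the dominant BBB transport direction.

    With a confidence interval: efflux if it lies entirely below 1, uptake
    entirely above, passive if it contains 1.  Without one, the point
    estimate decides, with a band of ``tolerance`` around 1 declared
    indeterminate.
    """
    if ci is not None:
        lo, hi = ci
        if not (lo <= k_p_uu <= hi):
            raise DataValidationError("point estimate outside its CI")
        if hi < 1.0:
            return "efflux"
        if lo > 1.0:
            return "uptake"
        return "passive"
    if abs(k_p_uu - 1.0) < tolerance:
        return "indeterminate"
    return "efflux" if k_p_uu < 1.0 else "uptake"


@dataclass
class NeuroPKResult:
    """Per-region pharmacokinetic estimates with dispersion."""

    region_label: str
    c_tot_invivo: float         # ng g-1, mean over subjects
    c_tot_invivo_sd: float
    c_tot_slice: float          # ng g-1, mean over slice replicates
    c_tot_slice_sd: float
    v_u: float                  # mL g-1
    k_p: float | None
    k_p_uu: float
    k_p_uu_sd: float
    cf: float
    c_u_isf: float              # ng mL-1
    n_subjects: int
    n_slices: int
    transport_class: str
    unreliable: bool = False    # a below-LLOQ operand entered a ratio

    def to_dict(self) -> dict:
        return {
            "region": self.region_label,
            "C_tot_invivo_ng_per_g": self.c_tot_invivo,
            "C_tot_invivo_sd": self.c_tot_invivo_sd,
            "C_tot_slice_ng_per_g": self.c_tot_slice,
            "C_tot_slice_sd": self.c_tot_slice_sd,
            "V_u_mL_per_g": self.v_u,
            "K_p": self.k_p,
            "K_p_uu": self.k_p_uu,
            "K_p_uu_sd": self.k_p_uu_sd,
            "CF": self.cf,
            "C_u_isf_ng_per_mL": self.c_u_isf,
            "n_subjects": self.n_subjects,
            "n_slices": self.n_slices,
            "transport_class": self.transport_class,
            "unreliable": self.unreliable,
        }


def _collect(results_per_section: Sequence[Mapping], region: str):
    vals, flags = [], []
    for table in results_per_section:
        if region not in table:
            raise AlignmentError(f"region {region!r} missing from a section")
        r = table[region]
        vals.append(r.concentration)
        flags.append(r.below_lloq or r.clipped)
    return np.asarray(vals, dtype=float), any(flags)


def build_kpuu_map(invivo: Sequence[Mapping[str, object]],
                   slices: Sequence[Mapping[str, object]],
                   cf: float = 1.0,
                   c_u_buffer: float | None = None,
                   c_tot_plasma: float | None = None,
                   ci_level: float = 0.95) -> tuple[pd.DataFrame, dict]:
    """Assemble the regional transport map from quantified sections.

    ``invivo`` and ``slices`` are per-section mappings region →
    :class:`~kpuumap.quantitation.RegionQuantResult` (one mapping per
    animal / slice replicate).  Each animal's regional concentration is
    divided by the mean slice concentration of that region; the per-region
    mean ± sd of those n ratios (× CF) is the reported K_p,uu.  V_u and
    K_p are filled in when buffer / plasma bulk levels are supplied.

    Returns the result table (one row per region) and the heat-map payload
    (region order, values, vmin/vmax set to the min/max regional means).
    """
    from scipy import stats as sps

    if not invivo or not slices:
        raise DataValidationError("need at least one section per condition")
    regions = list(invivo[0].keys())
    for table in list(invivo) + list(slices):
        if set(table.keys()) != set(regions):
            raise AlignmentError(
                "region labels do not align across sections")

    rows = []
    for region in regions:
        iv_vals, iv_flag = _collect(invivo, region)
        sl_vals, sl_flag = _collect(slices, region)
        sl_mean = float(sl_vals.mean())
        ratios = np.array([kpuu_ratio(v, sl_mean, cf) for v in iv_vals])
        k_mean = float(ratios.mean())
        k_sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
        if ratios.size > 1 and k_sd > 0:
            tcrit = float(sps.t.ppf(0.5 + ci_level / 2, ratios.size - 1))
            half = tcrit * k_sd / np.sqrt(ratios.size)
            ci = (k_mean - half, k_mean + half)
            tclass = classify_transport(k_mean, ci)
        else:
            tclass = classify_transport(k_mean)
        v_u = (v_u_brain_from_conc(sl_mean, c_u_buffer)
               if c_u_buffer else float("nan"))
        k_p = (kp_total(float(iv_vals.mean()), c_tot_plasma)
               if c_tot_plasma else None)
        c_isf = (unbound_isf_conc(float(iv_vals.mean()), v_u)
                 if c_u_buffer and v_u > 0 else float("nan"))
        rows.append(NeuroPKResult(
            region_label=region,
            c_tot_invivo=float(iv_vals.mean()),
            c_tot_invivo_sd=float(iv_vals.std(ddof=1)) if iv_vals.size > 1 else 0.0,
            c_tot_slice=sl_mean,
            c_tot_slice_sd=float(sl_vals.std(ddof=1)) if sl_vals.size > 1 else 0.0,
            v_u=v_u, k_p=k_p, k_p_uu=k_mean, k_p_uu_sd=k_sd, cf=cf,
            c_u_isf=c_isf, n_subjects=int(iv_vals.size),
            n_slices=int(sl_vals.size), transport_class=tclass,
            unreliable=iv_flag or sl_flag))

    table = pd.DataFrame([r.to_dict() for r in rows])
    means = table["K_p_uu"].to_numpy()
    heatmap = {"regions": regions, "values": means,
               "vmin": float(means.min()), "vmax": float(means.max())}
    return table, heatmap
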