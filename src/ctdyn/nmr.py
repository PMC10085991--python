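"""Per-residue NMR perturbation profiles from assigned HSQC peak lists.

Chemical-shift perturbation between two conditions uses the weighted
average of amide ¹H and ¹⁵N shift changes,

    Δδ_av = sqrt( (Δδ_H)² + (Δδ_N / 5)² )   [ppm]

with the nitrogen axis scaled by 1/5. Peak-intensity ratios (probe over
reference, e.g. receptor+Gs over receptor) and paramagnetic relaxation
enhancement profiles (I_para / I_dia around a spin label) are computed
per residue; replicate spectra yield mean ± s.e.m. Peaks are matched by
assigned residue number; residues absent from either list propagate as
explicit gaps (NaN + ``missing`` flag), never imputed as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EmptyOverlapError, InvalidArgumentError

NITROGEN_SCALE = 5.0

PEAKLIST_COLUMNS = ["residue", "dH_ppm", "dN_ppm", "intensity"]


def _validate_peaklist(peaks: pd.DataFrame, name: str = "peak list") -> pd.DataFrame:
    missing_cols = [c for c in ("residue", "dH_ppm", "dN_ppm") if c not in peaks]
    if missing_cols:
        raise InvalidArgumentError(f"{name} lacks columns {missing_cols}")
    if peaks["residue"].duplicated().any():
        raise InvalidArgumentError(f"{name} has duplicate residue numbers")
    if "intensity" in peaks and (peaks["intensity"].dropna() <= 0).any():
        raise InvalidArgumentError(f"{name} has non-positive intensities")
    return peaks.set_index("residue", drop=False)


def csp(delta_h, delta_n):
    """Weighted-average amide chemical-shift perturbation (ppm)."""
    dh = np.asarray(delta_h, float)
    dn = np.asarray(delta_n, float)
    return np.sqrt(dh**2 + (dn / NITROGEN_SCALE) ** 2)


def compute_csp(reference: pd.DataFrame, probe: pd.DataFrame) -> pd.DataFrame:
    """Per-residue Δδ_av between a reference and a probe peak list.

    Returns a DataFrame over the union of residues with columns
    (residue, delta_h, delta_n, csp_ppm, missing); residues present in
    only one list carry NaN and missing=True.
    """
    ref = _validate_peaklist(reference, "reference")
    prb = _validate_peaklist(probe, "probe")
    shared = ref.index.intersection(prb.index)
    if shared.empty:
        raise EmptyOverlapError("peak lists share no residues")
    union = ref.index.union(prb.index).sort_values()
    out = pd.DataFrame({"residue": union.to_numpy()}).set_index(union)
    out["delta_h"] = prb["dH_ppm"].reindex(union) - ref["dH_ppm"].reindex(union)
    out["delta_n"] = prb["dN_ppm"].reindex(union) - ref["dN_ppm"].reindex(union)
    out["csp_ppm"] = csp(out["delta_h"], out["delta_n"])
    out["missing"] = ~union.isin(shared)
    out.loc[out["missing"], ["delta_h", "delta_n", "csp_ppm"]] = np.nan
    return out.reset_index(drop=True)


def _ratio_track(reference: pd.DataFrame, probes, value: str = "intensity"):
    """Per-replicate probe/reference ratio matrix over the union of residues."""
    ref = _validate_peaklist(reference, "reference")
    if isinstance(probes, pd.DataFrame):
        probes = [probes]
    probes = [_validate_peaklist(p, f"probe {i}") for i, p in enumerate(probes)]
    union = ref.index
    for p in probes:
        union = union.union(p.index)
    union = union.sort_values()
    ref_i = ref[value].reindex(union)
    ratios = np.full((len(union), len(probes)), np.nan)
    for j, p in enumerate(probes):
        probe_i = p[value].reindex(union)
        ok = (ref_i > 0) & probe_i.notna() & ref_i.notna()
        ratios[ok.to_numpy(), j] = (probe_i[ok] / ref_i[ok]).to_numpy()
    return union, ratios


def _nan_mean_sem(mat: np.ndarray):
    """Row-wise mean, s.e.m. and count over finite entries (warning-free)."""
    finite = np.isfinite(mat)
    n = finite.sum(axis=1)
    safe = np.where(finite, mat, 0.0)
    mean = np.full(mat.shape[0], np.nan)
    has = n > 0
    mean[has] = safe[has].sum(axis=1) / n[has]
    sem = np.zeros(mat.shape[0])
    multi = n > 1
    if multi.any():
        dev2 = np.where(finite, (mat - mean[:, None]) ** 2, 0.0)
        sd = np.sqrt(dev2[multi].sum(axis=1) / (n[multi] - 1))
        sem[multi] = sd / np.sqrt(n[multi])
    return mean, sem, n


def intensity_ratio(reference: pd.DataFrame, probes) -> pd.DataFrame:
    """Per-residue probe/reference peak-intensity ratio.

    ``probes`` may be one peak list or a list of replicate lists; ratios
    are computed per replicate pair and then averaged (mean ± s.e.m.).
    Residues with zero/absent reference intensity are flagged, not
    divided.
    """
    union, ratios = _ratio_track(reference, probes)
    mean, sem, n = _nan_mean_sem(ratios)
    sem = np.where(n > 1, sem, np.nan)
    return pd.DataFrame(
        {
            "residue": union.to_numpy(),
            "iratio": np.where(n > 0, mean, np.nan),
            "iratio_sem": sem,
            "n_replicates": n,
            "missing": n == 0,
        }
    )


def pre_profile(para_replicates, dia_replicates) -> pd.DataFrame:
    """Per-residue PRE attenuation I_para / I_dia with replicate error.

    Both arguments are peak lists or lists of replicate peak lists. The
    ratio uses replicate-mean intensities; the error propagates the
    s.e.m. of each side (first-order). Residues missing from the
    diamagnetic set are flagged.
    """
    if isinstance(para_replicates, pd.DataFrame):
        para_replicates = [para_replicates]
    if isinstance(dia_replicates, pd.DataFrame):
        dia_replicates = [dia_replicates]
    if not para_replicates or not dia_replicates:
        raise InvalidArgumentError("need >= 1 replicate on each side")

    def stack(reps):
        reps = [_validate_peaklist(p, "replicate") for p in reps]
        union = reps[0].index
        for p in reps[1:]:
            union = union.union(p.index)
        union = union.sort_values()
        mat = np.column_stack([p["intensity"].reindex(union) for p in reps])
        return union, mat

    u_para, m_para = stack(para_replicates)
    u_dia, m_dia = stack(dia_replicates)
    union = u_para.union(u_dia).sort_values()

    def summarize(u, m):
        full = np.full((len(union), m.shape[1]), np.nan)
        full[union.isin(u)] = m
        return _nan_mean_sem(full)

    para_mean, para_sem, n_para = summarize(u_para, m_para)
    dia_mean, dia_sem, n_dia = summarize(u_dia, m_dia)

    ok = (n_para > 0) & (n_dia > 0) & (dia_mean > 0)
    ratio = np.full(len(union), np.nan)
    err = np.full(len(union), np.nan)
    ratio[ok] = para_mean[ok] / dia_mean[ok]
    err[ok] = ratio[ok] * np.sqrt(
        (para_sem[ok] / para_mean[ok]) ** 2 + (dia_sem[ok] / dia_mean[ok]) ** 2
    )
    return pd.DataFrame(
        {
            "residue": union.to_numpy(),
            "pre_ratio": ratio,
            "pre_sem": err,
            "missing": ~ok,
        }
    )
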