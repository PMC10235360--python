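"""Signature Index (SI) scoring, Z'-factor robustness and hit ranking.

The SI places each screened sample on the axis between the negative-control
state (KF, keloid fibroblast) and the positive-control state (AD, induced
adipocyte).  For gene i with mean control CPM G_iKF and G_iAD and sample j
with CPM G_ij:

    R_ij = (G_ij - G_iKF) / (G_iAD - G_iKF)     relative expression
    W_i  = | log2(G_iAD / G_iKF) |              gene weight
    SI_j = sum_i R_ij * W_i                     raw signature index

R_ij is 0 at the KF state and 1 at the AD state; genes moving opposite to
the AD direction contribute negatively.  The weight up-ranks strongly
differential genes regardless of absolute abundance, which is what lets
low-abundance fate regulators count alongside abundant structural genes.
Raw SIs are normalized to 0-1 by dividing by the screen maximum.

Assay robustness uses the standard screening-window coefficient

    Z' = 1 - 3 (sigma_pos + sigma_neg) / | mu_pos - mu_neg |

over control-well SIs; Z' > 0 marks a usable separation band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ControlProfiles:
    """Per-gene mean control CPM: the anchors of the reprogramming axis.

    Genes with G_iAD == G_iKF are flagged zero-weight and excluded from SI:
    the relative-expression denominator is singular there and the gene
    carries no directional signal.
    """

    gi_kf: pd.Series
    gi_ad: pd.Series
    kf_samples: list[str] = field(default_factory=list)
    ad_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gi_kf.index.equals(self.gi_ad.index):
            raise ValueError("control profiles must share one gene index")
        for s in (self.gi_kf, self.gi_ad):
            v = s.to_numpy(dtype=float)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError("control means must be finite and >= 0")

    @property
    def included(self) -> pd.Series:
        """Boolean mask of genes usable for SI (non-singular axis)."""
        return (self.gi_ad != self.gi_kf) & ~((self.gi_ad == 0) & (self.gi_kf == 0))

    @classmethod
    def from_cpm(cls, cpm_df: pd.DataFrame, roles: pd.Series,
                 aggregation: str = "mean") -> "ControlProfiles":
        """Aggregate control replicate CPM columns into G_iKF / G_iAD.

        ``roles`` maps sample_id -> {KF_control, AD_control, compound}.
        """
        agg = {"mean": np.mean, "median": np.median}[aggregation]
        kf_samples = [s for s in cpm_df.columns if roles.get(s) == "KF_control"]
        ad_samples = [s for s in cpm_df.columns if roles.get(s) == "AD_control"]
        if not kf_samples or not ad_samples:
            raise ValueError("need at least one KF_control and one AD_control sample")
        gi_kf = cpm_df[kf_samples].apply(agg, axis=1)
        gi_ad = cpm_df[ad_samples].apply(agg, axis=1)
        return cls(gi_kf=gi_kf, gi_ad=gi_ad, kf_samples=kf_samples, ad_samples=ad_samples)


def relative_expression(g_ij: float | np.ndarray | pd.Series,
                        gi_kf: float | np.ndarray | pd.Series,
                        gi_ad: float | np.ndarray | pd.Series):
    """R_ij = (G_ij - G_iKF) / (G_iAD - G_iKF); may fall outside [0, 1].

    A zero denominator yields NaN — the excluded-gene signal, handled (not
    raised) by the SI computation.
    """
    num = np.asarray(g_ij, dtype=float) - np.asarray(gi_kf, dtype=float)
    den = np.asarray(gi_ad, dtype=float) - np.asarray(gi_kf, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den == 0, np.nan, num / den)
    if isinstance(g_ij, pd.Series):
        return pd.Series(r, index=g_ij.index)
    return r if r.ndim else float(r)


def gene_weight(gi_kf: float, gi_ad: float, pseudocount: float = 0.0) -> float:
    """W_i = |log2((G_iAD + eps) / (G_iKF + eps))|.

    With the default eps=0, a single zero control mean falls back to eps=1
    (so the weight stays finite); both-zero genes return NaN, the
    excluded-gene signal.
    """
    eps = pseudocount
    if eps == 0.0 and (gi_kf == 0.0 or gi_ad == 0.0):
        if gi_kf == 0.0 and gi_ad == 0.0:
            return float("nan")
        eps = 1.0
    return float(abs(np.log2((gi_ad + eps) / (gi_kf + eps))))


def gene_weights(controls: ControlProfiles, pseudocount: float = 0.0) -> pd.Series:
    """Vector of W_i over the control gene index; excluded genes get 0."""
    w = pd.Series(
        [gene_weight(float(controls.gi_kf[g]), float(controls.gi_ad[g]), pseudocount)
         for g in controls.gi_kf.index],
        index=controls.gi_kf.index, name="weight")
    return w.where(controls.included, 0.0).fillna(0.0)


def signature_index(profile: pd.Series, controls: ControlProfiles,
                    pseudocount: float = 0.0) -> float:
    """Raw SI of one sample: the weighted sum of relative expressions.

    Genes flagged excluded (singular axis) contribute exactly zero.
    """
    inc = controls.included
    if not inc.any():
        raise ValueError("no gene has a usable KF->AD axis")
    w = gene_weights(controls, pseudocount)[inc]
    r = relative_expression(profile[inc.index][inc], controls.gi_kf[inc], controls.gi_ad[inc])
    return float((r * w).sum())


def signature_index_table(cpm_df: pd.DataFrame, controls: ControlProfiles,
                          pseudocount: float = 0.0) -> pd.Series:
    """Raw SI for every sample column of a gene-level CPM matrix."""
    inc = controls.included
    if not inc.any():
        raise ValueError("no gene has a usable KF->AD axis")
    genes = inc.index[inc]
    w = gene_weights(controls, pseudocount)[genes].to_numpy()
    kf = controls.gi_kf[genes].to_numpy()
    ad = controls.gi_ad[genes].to_numpy()
    g = cpm_df.loc[genes].to_numpy(dtype=float)
    r = (g - kf[:, None]) / (ad - kf)[:, None]
    return pd.Series(r.T @ w, index=cpm_df.columns, name="raw_si")


def normalize_si(raw: pd.Series, clip_negative: bool = True) -> tuple[pd.Series, bool]:
    """Scale raw SIs to 0-1 by the screen maximum; the max maps to exactly 1.

    Negative scaled values are clipped to 0 afterwards (division by the max
    cannot bound them); the returned flag reports whether clipping occurred.
    """
    m = float(raw.max())
    if m <= 0:
        raise ValueError("maximum raw SI is not positive; screen uninterpretable")
    norm = raw / m
    clipped = bool((norm < 0).any()) and clip_negative
    if clip_negative:
        norm = norm.clip(lower=0.0)
    return norm.rename("normalized_si"), clipped


@dataclass(frozen=True)
class ZPrimeReport:
    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float
    z_prime: float
    verdict: str


def z_prime(pos_sis, neg_sis) -> ZPrimeReport:
    """Screening-window coefficient over control SIs (sample SDs, ddof=1).

    Verdict bands: excellent (>= 0.5), acceptable (0, 0.5), poor (<= 0).
    Identical group means give -inf, reported as 'fail'.
    """
    pos = np.asarray(list(pos_sis), dtype=float)
    neg = np.asarray(list(neg_sis), dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least two control samples per group")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    sd_p, sd_n = float(pos.std(ddof=1)), float(neg.std(ddof=1))
    if mu_p == mu_n:
        return ZPrimeReport(mu_p, sd_p, mu_n, sd_n, float("-inf"), "fail")
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    verdict = "excellent" if z >= 0.5 else ("acceptable" if z > 0 else "poor")
    return ZPrimeReport(mu_p, sd_p, mu_n, sd_n, float(z), verdict)


def rank_hits(normalized: pd.Series, roles: pd.Series,
              near_hit_margin: float = 0.05) -> pd.DataFrame:
    """Rank compounds by normalized SI and call hits against the AD controls.

    A compound is a hit when its SI reaches the mean AD-control SI, and a
    near-hit when within ``near_hit_margin`` below it.  Ties in SI break by
    sample_id so the ranking is deterministic.
    """
    ad = [s for s in normalized.index if roles.get(s) == "AD_control"]
    if not ad:
        raise ValueError("no AD_control samples to set the hit threshold")
    threshold = float(normalized[ad].mean())
    compounds = [s for s in normalized.index if roles.get(s) == "compound"]
    df = pd.DataFrame({"sample_id": compounds,
                       "normalized_si": normalized[compounds].to_numpy()})
    df = df.sort_values(["normalized_si", "sample_id"],
                        ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["hit"] = df["normalized_si"] >= threshold
    df["near_hit"] = ~df["hit"] & (df["normalized_si"] >= threshold - near_hit_margin)
    df.attrs["ad_threshold"] = threshold
    return df


@dataclass
class SIResult:
    """Full screen scoring bundle."""

    weights: pd.Series
    raw_si: pd.Series
    normalized_si: pd.Series
    clipped: bool
    z_prime_report: ZPrimeReport
    hits: pd.DataFrame
    controls: ControlProfiles


def score_screen(cpm_df: pd.DataFrame, roles: pd.Series,
                 pseudocount: float = 0.0, clip_negative: bool = True,
                 near_hit_margin: float = 0.05,
                 aggregation: str = "mean") -> SIResult:
    """CPM matrix + sample roles -> SI table, Z' and ranked hits."""
    controls = ControlProfiles.from_cpm(cpm_df, roles, aggregation)
    raw = signature_index_table(cpm_df, controls)
    norm, clipped = normalize_si(raw, clip_negative)
    if clipped:
        warnings.warn("negative normalized SIs were clipped to 0", stacklevel=2)
    zp = z_prime(norm[controls.ad_samples], norm[controls.kf_samples])
    hits = rank_hits(norm, roles, near_hit_margin)
    return SIResult(gene_weights(controls, pseudocount), raw, norm, clipped, zp,
                    hits, controls)
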