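"""Module-trait association and the key-module coherence rule.

Each drug-vehicle contrast defines a binary trait over its eight samples
(0 = vehicle, 1 = drug).  A module's eigengene, restricted to those
samples, is correlated with the trait (Pearson; the trait is binary so a
robust correlation has nothing to gain), with a Student asymptotic p-value
and Benjamini-Hochberg correction across the full module x contrast
family.  A module is *key* when at least ``min_traits`` contrasts are
significant at the adjusted level AND those significant correlations share
one sign — coherent same-direction regulation by several drugs is read as
a common therapeutic mechanism rather than a single drug's off-target
effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import bh_adjust
from .simulate import SampleDesign

__all__ = ["trait_vector", "correlate", "adjust_and_flag", "module_trait_analysis"]


def trait_vector(design: SampleDesign, contrast: str) -> pd.Series:
    """Binary drug indicator over the contrast's samples (vehicle first)."""
    drug, vehicle = design.contrast_samples(contrast)
    return pd.Series(
        [0] * len(vehicle) + [1] * len(drug), index=vehicle + drug, name=contrast
    )


def correlate(eigengene: pd.Series, trait: pd.Series) -> tuple[float, float]:
    """Pearson r and two-sided Student asymptotic p for one module/trait.

    t = r * sqrt((n - 2) / (1 - r^2)) against the t distribution with
    n - 2 degrees of freedom; |r| = 1 yields p = 0 by convention.
    """
    e = eigengene.reindex(trait.index).to_numpy(dtype=float)
    t = trait.to_numpy(dtype=float)
    n = t.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(t) == 0:
        raise ValueError("trait is constant")
    if np.ptp(e) == 0:
        raise ValueError("eigengene is constant over the contrast samples")
    r = float(np.corrcoef(e, t)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(tstat), df=n - 2)
    return r, float(p)


def module_trait_analysis(
    eigengenes: pd.DataFrame, design: SampleDesign
) -> pd.DataFrame:
    """Correlation table over every (module, contrast) cell (no adjustment)."""
    rows = []
    for contrast in design.contrasts:
        trait = trait_vector(design, contrast)
        for m in eigengenes.index:
            r, p = correlate(eigengenes.loc[m], trait)
            rows.append({"module": m, "contrast": contrast, "r": r, "p": p})
    return pd.DataFrame(rows)


def adjust_and_flag(
    results: pd.DataFrame, alpha: float = 0.05, min_traits: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BH-adjust the module x contrast family and apply the key rule.

    Returns (cell table with ``adj_p`` and ``significant``, per-module
    summary with ``n_significant``, ``sign_pattern`` and ``key``).  The key
    flag requires >= ``min_traits`` significant contrasts whose correlation
    signs all agree.
    """
    out = results.copy()
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["adj_p"] < alpha
    summaries = []
    for m, grp in out.groupby("module"):
        sig = grp[grp["significant"]]
        signs = set(np.sign(sig["r"]).astype(int))
        coherent = len(sig) >= min_traits and len(signs) == 1
        summaries.append(
            {
                "module": m,
                "n_significant": int(len(sig)),
                "sign_pattern": "".join(
                    "+" if s > 0 else "-" for s in np.sign(sig["r"]).astype(int)
                ),
                "key": bool(coherent),
            }
        )
    return out, pd.DataFrame(summaries).set_index("module")
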