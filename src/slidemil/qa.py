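"""Artifact-bias quality assurance.

Non-biological slide defects (pen marks, folds, dots, ...) can correlate
with the class label — e.g. pen marks left by prior annotation of tumour
slides — and a weakly supervised model could learn them as shortcuts. This
module tabulates per-artifact prevalence by class and tests the
class-conditional proportions with a pooled-variance two-proportion
Z-test (two-sided, no continuity correction). A test is only run when at
least 15 slides carry the artifact, and significance is called against the
Bonferroni-corrected threshold alpha / m over the m artifacts tested
(0.05 / 7 = 0.0071 in the reference cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ProportionTestResult", "MIN_AFFECTED_FOR_TEST",
    "tabulate_prevalence", "two_proportion_ztest",
    "bonferroni_threshold", "qa_report",
]

MIN_AFFECTED_FOR_TEST = 15


@dataclass
class ProportionTestResult:
    z: float | None
    p_value: float | None
    tested: bool
    significant_after_bonferroni: bool = False


def _artifact_columns(manifest: pd.DataFrame):
    reserved = {"slide_id", "path", "label", "cohort", "mask_path"}
    return [c for c in manifest.columns if c not in reserved]


def tabulate_prevalence(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-artifact prevalence by class and overall.

    Expects a manifest with a binary ``label`` column (1 = tumour) and one
    0/1 column per artifact. Returns one row per artifact with
    tumour/normal/total fractions and the affected-slide count.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    tumour = manifest[manifest["label"] == 1]
    normal = manifest[manifest["label"] == 0]
    rows = []
    for name in _artifact_columns(manifest):
        flags = manifest[name].astype(int)
        rows.append({
            "artifact": name,
            "tumour_fraction": float(tumour[name].mean()) if len(tumour) else 0.0,
            "normal_fraction": float(normal[name].mean()) if len(normal) else 0.0,
            "total_fraction": float(flags.mean()),
            "n_affected": int(flags.sum()),
        })
    return pd.DataFrame(rows)


def two_proportion_ztest(p1: float, n1: int, p2: float, n2: int,
                         n_affected: int | None = None) -> ProportionTestResult:
    """Pooled-variance two-proportion Z-test, two-sided.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion;
    the p-value is the two-sided standard-normal tail. When ``n_affected``
    is given and falls below 15 the test is skipped (tested=False, no
    p-value), mirroring the minimum-count gate.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    for p in (p1, p2):
        if not 0 <= p <= 1:
            raise ValueError("proportions must be in [0, 1]")
    if n_affected is not None and n_affected < MIN_AFFECTED_FOR_TEST:
        return ProportionTestResult(z=None, p_value=None, tested=False)
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        z = 0.0
    else:
        z = (p1 - p2) / np.sqrt(var)
    p_value = float(2 * norm.sf(abs(z)))
    return ProportionTestResult(z=float(z), p_value=p_value, tested=True)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def qa_report(manifest: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Prevalence table + per-artifact tests + corrected significance calls.

    m is the number of artifacts that actually pass the >= 15 affected
    gate. Returns one row per artifact with fractions, z, p, tested and
    significant columns; the corrected threshold is attached as
    ``frame.attrs['bonferroni_threshold']``.
    """
    table = tabulate_prevalence(manifest)
    n_tumour = int((manifest["label"] == 1).sum())
    n_normal = int((manifest["label"] == 0).sum())
    results = []
    for _, row in table.iterrows():
        results.append(two_proportion_ztest(
            row["tumour_fraction"], max(n_tumour, 1),
            row["normal_fraction"], max(n_normal, 1),
            n_affected=int(row["n_affected"])))
    m = sum(r.tested for r in results)
    threshold = bonferroni_threshold(alpha, max(m, 1))
    table = table.copy()
    table["z"] = [r.z for r in results]
    table["p_value"] = [r.p_value for r in results]
    table["tested"] = [r.tested for r in results]
    table["significant"] = [
        bool(r.tested and r.p_value is not None and r.p_value < threshold)
        for r in results
    ]
    table.attrs["bonferroni_threshold"] = threshold
    table.attrs["m_tested"] = m
    table.attrs["n_tumour"] = n_tumour
    table.attrs["n_normal"] = n_normal
    return table
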