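"""Conformational chemical-shift and scalar-coupling classification.

The conformational (secondary) chemical shift is the observed shift minus
the random-coil reference for the same residue type.  For 13C-alpha, large
positive deviations (>= ~1 ppm) indicate alpha-helix, large negative ones
(<= ~-0.7 ppm) beta-strand, and near-zero values a statistical coil or PPII
helix.  The 3J(HN-HA) coupling discriminates the same way: couplings in the
5.5-8.0 Hz band are consistent with coil or PPII, smaller ones with
alpha-helix, larger with beta-strand.

NMR alone cannot separate PPII from statistical coil at residue level —
that distinction comes from CD — so the classifier deliberately merges the
two into a single ``coil_or_ppii`` label.  Missing data propagate as
not-applicable, never as zero.

The numeric delta-delta thresholds are configurable defaults in the spirit
of the published graphical criteria, not tabulated literature constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClassCriteria",
    "ShiftClassifier",
    "ShiftClassifierResults",
    "conformational_shift",
    "classify_residue",
    "segment_verdict",
    "coil_reference",
    "make_shift_table",
    "RANDOM_COIL_CA",
    "RANDOM_COIL_HA",
    "NO_ALPHA_BETA_VERDICT",
]

# Random-coil chemical shifts (ppm) for Xaa in unstructured peptides at
# near-neutral pH, 25 C (Wishart-style coil reference values; 13C-alpha
# referenced to DSS).  Packaged static table; no neighbour corrections.
RANDOM_COIL_CA: dict[str, float] = {
    "A": 52.5, "R": 56.0, "N": 53.1, "D": 54.2, "C": 58.2,
    "Q": 55.7, "E": 56.6, "G": 45.1, "H": 55.0, "I": 61.1,
    "L": 55.1, "K": 56.2, "M": 55.4, "F": 57.7, "P": 63.3,
    "S": 58.3, "T": 61.8, "W": 57.5, "Y": 57.9, "V": 62.2,
}

RANDOM_COIL_HA: dict[str, float] = {
    "A": 4.32, "R": 4.34, "N": 4.74, "D": 4.64, "C": 4.71,
    "Q": 4.34, "E": 4.35, "G": 3.96, "H": 4.60, "I": 4.17,
    "L": 4.34, "K": 4.32, "M": 4.48, "F": 4.62, "P": 4.42,
    "S": 4.47, "T": 4.35, "W": 4.66, "Y": 4.55, "V": 4.12,
}

NO_ALPHA_BETA_VERDICT = "no alpha/beta; coil-or-PPII"

SHIFT_COLUMNS = [
    "residue_index", "aa", "ca_obs_ppm", "ca_ref_ppm",
    "ha_obs_ppm", "ha_ref_ppm", "j_hnha_hz",
]


@dataclass(frozen=True)
class ClassCriteria:
    """Numeric cutoffs for residue-level conformational classification.

    ``dca_*`` thresholds act on the 13C-alpha conformational shift in ppm;
    the J band [j_coil_lo, j_coil_hi] in Hz is the coupling range consistent
    with statistical coil or PPII.
    """

    dca_alpha_min: float = 1.0
    dca_beta_max: float = -0.7
    dca_coil_band: float = 0.4
    j_coil_lo: float = 5.5
    j_coil_hi: float = 8.0

    def __post_init__(self) -> None:
        if not (self.dca_beta_max < 0.0 < self.dca_alpha_min):
            raise ValueError("require dca_beta_max < 0 < dca_alpha_min")
        if not self.j_coil_lo < self.j_coil_hi:
            raise ValueError("require j_coil_lo < j_coil_hi")
        if self.dca_coil_band <= 0:
            raise ValueError("dca_coil_band must be positive")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def conformational_shift(obs: float | None, ref: float | None) -> float:
    """Delta-delta = observed minus random-coil reference, in ppm.

    Returns NaN (not-applicable) when either member is missing; a missing
    shift is never treated as zero.
    """
    if _missing(obs) or _missing(ref):
        return float("nan")
    return float(obs) - float(ref)


def classify_residue(
    dca: float | None, j: float | None, criteria: ClassCriteria | None = None
) -> str:
    """Classify one residue as alpha, beta, coil_or_ppii, or ambiguous.

    alpha: dca >= dca_alpha_min and J (if present) below the coil band.
    beta: dca <= dca_beta_max and J (if present) above the coil band.
    coil_or_ppii: |dca| within the coil band and J (if present) inside it.
    Anything else — including a shift between the coil band and a
    secondary-structure threshold, or contradictory shift/coupling evidence
    — is ambiguous.  Raises when both inputs are missing.
    """
    c = criteria if criteria is not None else ClassCriteria()
    dca_na, j_na = _missing(dca), _missing(j)
    if dca_na and j_na:
        raise ValueError("cannot classify a residue with no shift and no coupling")
    if not dca_na:
        if dca >= c.dca_alpha_min and (j_na or j < c.j_coil_lo):
            return "alpha"
        if dca <= c.dca_beta_max and (j_na or j > c.j_coil_hi):
            return "beta"
        if abs(dca) <= c.dca_coil_band and (j_na or c.j_coil_lo <= j <= c.j_coil_hi):
            return "coil_or_ppii"
    return "ambiguous"


def segment_verdict(
    table: pd.DataFrame,
    criteria: ClassCriteria | None = None,
    reject_threshold: float = 0.1,
    ambiguous_threshold: float = 0.5,
) -> dict:
    """Per-class residue fractions and an overall verdict for a peptide.

    Residues lacking both a conformational shift and a coupling are left
    unclassified (and excluded from the fractions).  The verdict is
    "no alpha/beta; coil-or-PPII" when the alpha and beta fractions both
    fall below ``reject_threshold`` and fewer than ``ambiguous_threshold``
    of the residues are ambiguous — a confident coil/PPII call needs most
    residues actually inside the coil band.  Otherwise the verdict names
    what blocked it.
    """
    c = criteria if criteria is not None else ClassCriteria()
    if table is None or len(table) == 0:
        raise ValueError("empty shift table")

    labels = []
    for _, row in table.iterrows():
        dca = conformational_shift(row.get("ca_obs_ppm"), row.get("ca_ref_ppm"))
        j = row.get("j_hnha_hz", float("nan"))
        if _missing(dca) and _missing(j):
            labels.append("unclassified")
            continue
        labels.append(classify_residue(None if _missing(dca) else dca,
                                       None if _missing(j) else j, c))
    classified = [x for x in labels if x != "unclassified"]
    if not classified:
        raise ValueError("no residue has both data members missing-free; nothing to classify")
    n = len(classified)
    fractions = {
        lab: classified.count(lab) / n
        for lab in ("alpha", "beta", "coil_or_ppii", "ambiguous")
    }
    if fractions["alpha"] >= reject_threshold or fractions["beta"] >= reject_threshold:
        verdict = (
            f"secondary structure detected (alpha {fractions['alpha']:.2f}, "
            f"beta {fractions['beta']:.2f})"
        )
    elif fractions["ambiguous"] >= ambiguous_threshold:
        verdict = f"inconclusive (ambiguous fraction {fractions['ambiguous']:.2f})"
    else:
        verdict = NO_ALPHA_BETA_VERDICT
    return {
        "fractions": fractions,
        "verdict": verdict,
        "labels": labels,
        "n_classified": n,
    }


def coil_reference(
    sequence: str,
    temperature: float = 25.0,
    ca_temp_coeff: float = 0.0,
    ha_temp_coeff: float = 0.0,
) -> pd.DataFrame:
    """Per-residue random-coil 13C-alpha and 1H-alpha references.

    Values come from the packaged coil table (25 C reference state, no
    neighbour corrections).  An optional linear temperature correction,
    ``ref(T) = ref(25) + coeff * (T - 25)`` in ppm, is applied uniformly;
    the default coefficients of 0 disable it.  Nonstandard residues are an
    error naming the position.
    """
    rows = []
    for i, aa in enumerate(sequence, start=1):
        code = aa.upper()
        if code not in RANDOM_COIL_CA:
            raise ValueError(f"nonstandard residue {aa!r} at position {i}")
        rows.append(
            (
                i,
                code,
                RANDOM_COIL_CA[code] + ca_temp_coeff * (temperature - 25.0),
                RANDOM_COIL_HA[code] + ha_temp_coeff * (temperature - 25.0),
            )
        )
    df = pd.DataFrame(rows, columns=["residue_index", "aa", "ca_ref_ppm", "ha_ref_ppm"])
    df.attrs["provenance"] = (
        "packaged Wishart-style random-coil table, 25 C reference; "
        f"linear T correction ca={ca_temp_coeff} ha={ha_temp_coeff} ppm/C "
        f"applied at T={temperature} C"
    )
    return df


def make_shift_table(
    sequence: str,
    ca_obs: list[float] | np.ndarray,
    j_hnha: list[float] | np.ndarray | None = None,
    ha_obs: list[float] | np.ndarray | None = None,
    temperature: float = 25.0,
) -> pd.DataFrame:
    """Assemble a shift table with coil references filled from the sequence."""
    ref = coil_reference(sequence, temperature)
    n = len(sequence)
    df = pd.DataFrame(
        {
            "residue_index": ref["residue_index"],
            "aa": ref["aa"],
            "ca_obs_ppm": np.asarray(ca_obs, dtype=float),
            "ca_ref_ppm": ref["ca_ref_ppm"],
            "ha_obs_ppm": (
                np.asarray(ha_obs, dtype=float) if ha_obs is not None else np.full(n, np.nan)
            ),
            "ha_ref_ppm": ref["ha_ref_ppm"],
            "j_hnha_hz": (
                np.asarray(j_hnha, dtype=float) if j_hnha is not None else np.full(n, np.nan)
            ),
        }
    )
    return df


class ShiftClassifier:
    """Residue-level conformational classifier for one peptide's shift table.

    Parameters
    ----------
    table
        DataFrame with columns residue_index, aa, ca_obs_ppm, ca_ref_ppm,
        optionally ha_obs_ppm/ha_ref_ppm, j_hnha_hz; NaN marks missing data.
    criteria
        Numeric classification cutoffs.
    """

    def __init__(self, table: pd.DataFrame, criteria: ClassCriteria | None = None):
        if table is None or len(table) == 0:
            raise ValueError("empty shift table")
        self.table = table.reset_index(drop=True)
        self.criteria = criteria if criteria is not None else ClassCriteria()
        self._validate()

    def _validate(self) -> None:
        for col, lo, hi in (
            ("ca_obs_ppm", 40.0, 70.0),
            ("ca_ref_ppm", 40.0, 70.0),
            ("ha_obs_ppm", 3.0, 6.0),
            ("ha_ref_ppm", 3.0, 6.0),
            ("j_hnha_hz", 0.0, 12.0),
        ):
            if col not in self.table.columns:
                continue
            vals = self.table[col].to_numpy(dtype=float)
            bad = vals[np.isfinite(vals) & ((vals < lo) | (vals > hi))]
            if bad.size:
                raise ValueError(
                    f"{col} value {bad[0]} outside the plausible range [{lo}, {hi}]"
                )
        idx = self.table["residue_index"].to_numpy()
        if len(np.unique(idx)) != len(idx) or np.any(np.diff(idx) <= 0):
            raise ValueError("residue_index must be unique and increasing")

    def fit(self, reject_threshold: float = 0.1) -> "ShiftClassifierResults":
        t = self.table.copy()
        t["dca_ppm"] = [
            conformational_shift(o, r)
            for o, r in zip(t["ca_obs_ppm"], t["ca_ref_ppm"])
        ]
        if "ha_obs_ppm" in t.columns and "ha_ref_ppm" in t.columns:
            t["dha_ppm"] = [
                conformational_shift(o, r)
                for o, r in zip(t["ha_obs_ppm"], t["ha_ref_ppm"])
            ]
        summary = segment_verdict(t, self.criteria, reject_threshold)
        t["class"] = summary["labels"]
        return ShiftClassifierResults(
            model=self,
            per_residue=t,
            fractions=summary["fractions"],
            verdict=summary["verdict"],
            n_classified=summary["n_classified"],
        )


@dataclass
class ShiftClassifierResults:
    """Per-residue conformational classes with segment-level fractions."""

    model: ShiftClassifier
    per_residue: pd.DataFrame
    fractions: dict[str, float]
    verdict: str
    n_classified: int

    def summary(self) -> str:
        c = self.model.criteria
        lines = [
            "NMR conformational classification",
            f"  residues: {len(self.per_residue)}   classified: {self.n_classified}",
            f"  criteria: dCa >= {c.dca_alpha_min:+.2f} ppm -> alpha,"
            f" <= {c.dca_beta_max:+.2f} ppm -> beta,"
            f" |dCa| <= {c.dca_coil_band:.2f} ppm with J in"
            f" [{c.j_coil_lo:g}, {c.j_coil_hi:g}] Hz -> coil/PPII",
            "",
            f"  {'class':<14}{'fraction':>10}",
        ]
        for lab, frac in self.fractions.items():
            lines.append(f"  {lab:<14}{frac:>10.3f}")
        lines += ["", f"  verdict: {self.verdict}"]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Conformational-shift bars with the coupling band (Fig-2a style)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.per_residue
        ax.bar(t["residue_index"], t["dca_ppm"], color="black", label=r"$\Delta\delta\,^{13}C\alpha$")
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("residue")
        ax.set_ylabel(r"$\Delta\delta\,^{13}C\alpha$ (ppm)")
        if t["j_hnha_hz"].notna().any():
            ax2 = ax.twinx()
            ax2.plot(t["residue_index"], t["j_hnha_hz"], "d", color="tab:blue")
            c = self.model.criteria
            ax2.axhline(c.j_coil_lo, color="tab:blue", ls="--", lw=0.8)
            ax2.axhline(c.j_coil_hi, color="tab:blue", ls="--", lw=0.8)
            ax2.set_ylabel(r"$^3J_{HN H\alpha}$ (Hz)")
        return ax
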