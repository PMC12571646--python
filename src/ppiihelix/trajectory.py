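"""PPII content statistics over dihedral ensembles.

Turns per-frame (phi, psi) classifications into the summary statistics used
to characterise chaperonin C-terminal tails in simulation ensembles:

* windowed content — the fraction of PPII-classified observations over the
  trailing time window (default 50 ns) ending at each report time, per chain
  and per named segment;
* per-repeat content — the same windowed estimator restricted to each
  three-residue GGM repeat, pooled over chains;
* per-residue population — mean PPII indicator per residue over the whole
  run;
* run summary — a single observation-weighted content value per segment.

Fractions are computed per observation: the denominator counts (frame,
residue) pairs with both dihedrals defined, so chain termini (which lack phi
or psi) never bias a segment's content.  Every reported fraction carries its
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import BackboneCoordinates, PPIIWindow, chain_dihedrals

__all__ = [
    "DihedralEnsemble",
    "SegmentMap",
    "TrajectoryPPII",
    "TrajectoryPPIIResults",
    "windowed_content",
    "per_residue_population",
    "per_repeat_content",
    "run_summary",
    "GROEL_CTC",
    "GROEL_CTS",
    "REPEAT_NAMES",
]

#: GroEL 24-residue C-terminal tail (solubility tags excluded: they are not
#: part of the protein).
GROEL_CTC = "PKNDAADLGAAGGMGGMGGMGGMM"
#: The short Gly/Met-rich stretch: the last 14 residues of the tail.
GROEL_CTS = "AGGMGGMGGMGGMM"

REPEAT_NAMES = ("GGM1", "GGM2", "GGM3", "GGM4")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def three_to_one(resname: str) -> str:
    return _THREE_TO_ONE.get(resname.upper(), "X")


def one_to_three(code: str) -> str:
    return _ONE_TO_THREE.get(code.upper(), "UNK")


@dataclass
class DihedralEnsemble:
    """Per-frame, per-chain, per-residue (phi, psi) angles on a shared time axis.

    ``phi`` and ``psi`` map chain label -> (n_frames, n_residues) float
    arrays in degrees with NaN for undefined terminus angles; ``sequence``
    maps chain label -> 1-letter residue string.
    """

    chains: list[str]
    times: np.ndarray
    phi: dict[str, np.ndarray]
    psi: dict[str, np.ndarray]
    sequence: dict[str, str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        nf = len(self.times)
        for chain in self.chains:
            for name, table in (("phi", self.phi), ("psi", self.psi)):
                arr = np.asarray(table[chain], dtype=float)
                table[chain] = arr
                nres = len(self.sequence[chain])
                if arr.shape != (nf, nres):
                    raise ValueError(
                        f"{name}[{chain!r}] has shape {arr.shape}, "
                        f"expected ({nf}, {nres})"
                    )

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def n_residues(self, chain: str) -> int:
        return len(self.sequence[chain])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DihedralEnsemble":
        """Build from a long-format dihedral table.

        Expected columns: frame, time_ns, chain, residue_index (1-based),
        residue_name, phi_deg, psi_deg; undefined angles as NaN.
        """
        required = {"frame", "time_ns", "chain", "residue_index", "phi_deg", "psi_deg"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dihedral table missing columns: {sorted(missing)}")
        for col in ("phi_deg", "psi_deg"):
            vals = df[col].to_numpy(dtype=float)
            bad = vals[np.isfinite(vals) & ((vals <= -180.0) | (vals > 180.0))]
            if bad.size:
                raise ValueError(
                    f"{col} contains values outside (-180, 180], e.g. {bad[0]}"
                )

        chains = list(dict.fromkeys(df["chain"].astype(str)))
        frame_times = (
            df[["frame", "time_ns"]].drop_duplicates().sort_values("frame")
        )
        times = frame_times["time_ns"].to_numpy(dtype=float)
        frame_order = {f: i for i, f in enumerate(frame_times["frame"])}

        phi: dict[str, np.ndarray] = {}
        psi: dict[str, np.ndarray] = {}
        sequence: dict[str, str] = {}
        for chain, sub in df.groupby("chain", sort=False):
            chain = str(chain)
            idx = np.sort(sub["residue_index"].unique())
            if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
                raise ValueError(f"chain {chain!r} residue indices are not 1..n")
            nres = len(idx)
            p = np.full((len(times), nres), np.nan)
            s = np.full((len(times), nres), np.nan)
            rows = sub["frame"].map(frame_order).to_numpy()
            cols = sub["residue_index"].to_numpy(dtype=int) - 1
            p[rows, cols] = sub["phi_deg"].to_numpy(dtype=float)
            s[rows, cols] = sub["psi_deg"].to_numpy(dtype=float)
            phi[chain], psi[chain] = p, s
            if "residue_name" in sub.columns:
                names = (
                    sub.drop_duplicates("residue_index")
                    .sort_values("residue_index")["residue_name"]
                    .astype(str)
                )
                sequence[chain] = "".join(
                    c if len(c) == 1 else three_to_one(c) for c in names
                )
            else:
                sequence[chain] = "X" * nres
        return cls(chains=chains, times=times, phi=phi, psi=psi, sequence=sequence)

    @classmethod
    def from_models(
        cls, models: list[BackboneCoordinates], dt_ns: float = 1.0
    ) -> "DihedralEnsemble":
        """Build from per-model backbone coordinates (e.g. a multi-model PDB).

        Frame time is ``model_index * dt_ns``; models sharing an index are
        one frame's worth of chains.
        """
        if not models:
            raise ValueError("no models supplied")
        frames = sorted({m.model_index for m in models})
        chains = list(dict.fromkeys(m.chain_id for m in models))
        times = np.asarray(frames, dtype=float) * dt_ns
        frame_row = {f: i for i, f in enumerate(frames)}

        phi: dict[str, np.ndarray] = {}
        psi: dict[str, np.ndarray] = {}
        sequence: dict[str, str] = {}
        for m in models:
            seq = "".join(three_to_one(r) for r in m.residue_names)
            sequence.setdefault(m.chain_id, seq)
            if sequence[m.chain_id] != seq:
                raise ValueError(
                    f"chain {m.chain_id!r} changes sequence across models"
                )
            nres = len(m)
            phi.setdefault(m.chain_id, np.full((len(frames), nres), np.nan))
            psi.setdefault(m.chain_id, np.full((len(frames), nres), np.nan))
            pairs = chain_dihedrals(m)
            row = frame_row[m.model_index]
            phi[m.chain_id][row] = [p.phi for p in pairs]
            psi[m.chain_id][row] = [p.psi for p in pairs]
        return cls(chains=chains, times=times, phi=phi, psi=psi, sequence=sequence)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format dihedral table (the TSV dialect's in-memory form)."""
        records = []
        for chain in self.chains:
            seq = self.sequence[chain]
            p, s = self.phi[chain], self.psi[chain]
            for fi, t in enumerate(self.times):
                for ri in range(len(seq)):
                    records.append(
                        (fi, t, chain, ri + 1, seq[ri], p[fi, ri], s[fi, ri])
                    )
        return pd.DataFrame.from_records(
            records,
            columns=[
                "frame", "time_ns", "chain", "residue_index",
                "residue_name", "phi_deg", "psi_deg",
            ],
        )


@dataclass
class SegmentMap:
    """Named 1-based residue subsets of each chain (CtC, CtS, GGM repeats)."""

    segments: dict[str, dict[str, tuple[int, ...]]]

    def __post_init__(self) -> None:
        for chain, segs in self.segments.items():
            for name, pos in segs.items():
                pos = tuple(int(p) for p in pos)
                segs[name] = pos
                if len(pos) == 0:
                    raise ValueError(f"segment {name!r} of chain {chain!r} is empty")
                if min(pos) < 1:
                    raise ValueError(f"segment {name!r} uses non-positive positions")
            repeats = [segs[n] for n in REPEAT_NAMES if n in segs]
            if repeats:
                flat = [p for r in repeats for p in r]
                if len(set(flat)) != len(flat):
                    raise ValueError(f"GGM repeats overlap in chain {chain!r}")
                if any(len(r) != 3 for r in repeats):
                    raise ValueError("each GGM repeat must have exactly 3 residues")

    def positions(self, chain: str, name: str) -> tuple[int, ...]:
        try:
            return self.segments[chain][name]
        except KeyError:
            raise KeyError(f"segment {name!r} not defined for chain {chain!r}") from None

    def names(self) -> list[str]:
        out: list[str] = []
        for segs in self.segments.values():
            for name in segs:
                if name not in out:
                    out.append(name)
        return out

    def has(self, name: str) -> bool:
        return any(name in segs for segs in self.segments.values())

    def chains_with(self, name: str) -> list[str]:
        return [c for c, segs in self.segments.items() if name in segs]

    @classmethod
    def from_sequences(cls, sequence: dict[str, str]) -> "SegmentMap":
        """Canonical CtC/CtS/GGM assignments inferred from chain sequences.

        A chain containing the Gly/Met-rich stretch AGGMGGMGGMGGMM gets CtS
        over that stretch, GGM1-4 at CtS positions 2-4, 5-7, 8-10, 11-13
        (the final MM belongs to no repeat), and CtC over the whole chain.
        Chains without the stretch get a single whole-chain segment "all".
        """
        segments: dict[str, dict[str, tuple[int, ...]]] = {}
        for chain, seq in sequence.items():
            segs: dict[str, tuple[int, ...]] = {}
            start = seq.find(GROEL_CTS)
            if start >= 0:
                offset = start + 1  # 1-based position of CtS residue 1
                segs["CtC"] = tuple(range(1, len(seq) + 1))
                segs["CtS"] = tuple(range(offset, offset + len(GROEL_CTS)))
                for k, name in enumerate(REPEAT_NAMES):
                    lo = offset + 1 + 3 * k  # CtS position 2 + 3k
                    segs[name] = tuple(range(lo, lo + 3))
            else:
                segs["all"] = tuple(range(1, len(seq) + 1))
            segments[chain] = segs
        return cls(segments=segments)

    @classmethod
    def from_ranges(
        cls, chains: list[str], ranges: dict[str, tuple[int, int]]
    ) -> "SegmentMap":
        """Same 1-based inclusive ranges applied to every chain."""
        segs = {
            name: tuple(range(int(lo), int(hi) + 1)) for name, (lo, hi) in ranges.items()
        }
        return cls(segments={c: dict(segs) for c in chains})


# ---------------------------------------------------------------------------
# estimation internals

def _classify(ens: DihedralEnsemble, window: PPIIWindow):
    """Per-chain (inside, defined) boolean arrays of shape (n_frames, n_res)."""
    inside: dict[str, np.ndarray] = {}
    defined: dict[str, np.ndarray] = {}
    for chain in ens.chains:
        p, s = ens.phi[chain], ens.psi[chain]
        d = np.isfinite(p) & np.isfinite(s)
        inside[chain] = np.asarray(window.contains(p, s)) & d
        defined[chain] = d
    return inside, defined


def _report_times(times: np.ndarray, window_ns: float, stride_ns: float) -> np.ndarray:
    if window_ns <= 0 or stride_ns <= 0:
        raise ValueError("window_ns and stride_ns must be positive")
    t_end = times[-1]
    eps = 1e-9 * max(1.0, abs(t_end))
    ts = np.arange(window_ns, t_end + eps + stride_ns, stride_ns)
    ts = ts[ts <= t_end + eps]
    if ts.size == 0:
        raise ValueError(
            f"trajectory ends at {t_end} ns, before the first {window_ns} ns window"
        )
    return ts


def _window_mask(times: np.ndarray, t: float, window_ns: float) -> np.ndarray:
    eps = 1e-9 * max(1.0, abs(t))
    return (times > t - window_ns + eps) & (times <= t + eps)


def windowed_content(
    ens: DihedralEnsemble,
    seg: SegmentMap,
    segment_name: str,
    window_ns: float = 50.0,
    stride_ns: float = 50.0,
    window: PPIIWindow | None = None,
) -> pd.DataFrame:
    """Trailing-window PPII content per chain for a named segment.

    Report times are multiples of ``stride_ns`` starting at ``window_ns``;
    the window at time t covers frames with time in (t - window_ns, t], so
    the value reported at 50 ns is the average over 0-50 ns.  A trailing
    partial window is dropped.  Columns: chain, segment, time_ns, fraction,
    n_obs.
    """
    w = window if window is not None else PPIIWindow()
    chains = seg.chains_with(segment_name)
    if not chains:
        raise KeyError(f"segment {segment_name!r} not defined in the segment map")
    inside, defined = _classify(ens, w)
    ts = _report_times(ens.times, window_ns, stride_ns)

    rows = []
    for chain in chains:
        cols = np.asarray(seg.positions(chain, segment_name)) - 1
        if cols.size == 0:
            raise ValueError(f"segment {segment_name!r} has no residues in {chain!r}")
        for t in ts:
            mask = _window_mask(ens.times, t, window_ns)
            if not mask.any():
                raise ValueError(f"window ending at {t} ns contains no frames")
            n_obs = int(defined[chain][np.ix_(mask, cols)].sum())
            n_ppii = int(inside[chain][np.ix_(mask, cols)].sum())
            frac = n_ppii / n_obs if n_obs else np.nan
            rows.append((chain, segment_name, float(t), frac, n_obs))
    return pd.DataFrame(rows, columns=["chain", "segment", "time_ns", "fraction", "n_obs"])


def per_residue_population(
    ens: DihedralEnsemble, window: PPIIWindow | None = None
) -> pd.DataFrame:
    """Whole-run mean PPII population per (chain, residue).

    Residues with no defined-dihedral observations (chain termini) report
    NaN (not applicable), never 0.  Columns: chain, residue_index,
    residue_name, mean_fraction, n_obs.
    """
    w = window if window is not None else PPIIWindow()
    inside, defined = _classify(ens, w)
    rows = []
    for chain in ens.chains:
        seq = ens.sequence[chain]
        n_obs = defined[chain].sum(axis=0)
        n_ppii = inside[chain].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_obs > 0, n_ppii / np.maximum(n_obs, 1), np.nan)
        for ri in range(len(seq)):
            rows.append((chain, ri + 1, seq[ri], frac[ri], int(n_obs[ri])))
    return pd.DataFrame(
        rows, columns=["chain", "residue_index", "residue_name", "mean_fraction", "n_obs"]
    )


def per_repeat_content(
    ens: DihedralEnsemble,
    seg: SegmentMap,
    window_ns: float = 50.0,
    stride_ns: float = 50.0,
    window: PPIIWindow | None = None,
) -> pd.DataFrame:
    """Windowed PPII content of each GGM repeat, pooled over all chains.

    Columns: segment, time_ns, fraction, n_obs.
    """
    present = [n for n in REPEAT_NAMES if seg.has(n)]
    if not present:
        raise ValueError("segment map defines no GGM repeats")
    frames = []
    for name in present:
        df = windowed_content(ens, seg, name, window_ns, stride_ns, window)
        pooled = (
            df.assign(n_ppii=lambda d: d["fraction"] * d["n_obs"])
            .groupby("time_ns", as_index=False)
            .agg(n_ppii=("n_ppii", "sum"), n_obs=("n_obs", "sum"))
        )
        pooled["fraction"] = pooled["n_ppii"] / pooled["n_obs"]
        pooled["segment"] = name
        frames.append(pooled[["segment", "time_ns", "fraction", "n_obs"]])
    return pd.concat(frames, ignore_index=True)


def run_summary(
    windowed: pd.DataFrame, segment_name: str, weights: str = "obs"
) -> float:
    """Scalar time-averaged PPII content for one segment.

    ``weights="obs"`` (default) is the observation-weighted mean over all
    windows and chains; ``weights="chain"`` first averages each chain
    (observation-weighted over its windows), then averages chains equally.
    """
    sub = windowed[windowed["segment"] == segment_name]
    if sub.empty:
        raise KeyError(f"no windowed results for segment {segment_name!r}")
    if weights == "obs":
        return float((sub["fraction"] * sub["n_obs"]).sum() / sub["n_obs"].sum())
    if weights == "chain":
        if "chain" not in sub.columns:
            raise ValueError("chain-weighted summary needs per-chain windowed results")
        per_chain = sub.groupby("chain").apply(
            lambda d: (d["fraction"] * d["n_obs"]).sum() / d["n_obs"].sum(),
            include_groups=False,
        )
        return float(per_chain.mean())
    raise ValueError("weights must be 'obs' or 'chain'")


# ---------------------------------------------------------------------------
# model / results interface

class TrajectoryPPII:
    """PPII-content estimator for a dihedral ensemble.

    Parameters
    ----------
    ensemble
        The (phi, psi) ensemble to analyse.
    segments
        Residue subsets to aggregate over; inferred from the chain sequences
        when omitted.
    window
        The (phi, psi) acceptance window; the -75/+150 +/- 20 deg PPII
        window by default.
    window_ns, stride_ns
        Width and spacing of the trailing averaging windows in ns.
    """

    def __init__(
        self,
        ensemble: DihedralEnsemble,
        segments: SegmentMap | None = None,
        window: PPIIWindow | None = None,
        window_ns: float = 50.0,
        stride_ns: float = 50.0,
    ):
        self.ensemble = ensemble
        self.segments = (
            segments
            if segments is not None
            else SegmentMap.from_sequences(ensemble.sequence)
        )
        self.window = window if window is not None else PPIIWindow()
        self.window_ns = float(window_ns)
        self.stride_ns = float(stride_ns)

    def fit(self) -> "TrajectoryPPIIResults":
        per_res = per_residue_population(self.ensemble, self.window)
        windowed_frames = []
        for name in self.segments.names():
            if name in REPEAT_NAMES:
                continue
            windowed_frames.append(
                windowed_content(
                    self.ensemble, self.segments, name,
                    self.window_ns, self.stride_ns, self.window,
                )
            )
        windowed = pd.concat(windowed_frames, ignore_index=True)
        repeats = None
        if any(self.segments.has(n) for n in REPEAT_NAMES):
            repeats = per_repeat_content(
                self.ensemble, self.segments, self.window_ns, self.stride_ns, self.window
            )
        return TrajectoryPPIIResults(
            model=self, per_residue=per_res, windowed=windowed, per_repeat=repeats
        )


@dataclass
class TrajectoryPPIIResults:
    """Fitted PPII content: per-residue, windowed per-segment, per-repeat."""

    model: TrajectoryPPII
    per_residue: pd.DataFrame
    windowed: pd.DataFrame
    per_repeat: pd.DataFrame | None = None

    def run_summary(self, segment_name: str, weights: str = "obs") -> float:
        return run_summary(self.windowed, segment_name, weights)

    def segment_names(self) -> list[str]:
        return list(self.windowed["segment"].unique())

    def summary(self) -> str:
        lines = [
            "PPII content summary",
            f"  frames: {self.model.ensemble.n_frames}"
            f"  chains: {len(self.model.ensemble.chains)}"
            f"  window: {self.model.window_ns} ns / stride {self.model.stride_ns} ns",
            f"  classification window: phi {self.model.window.phi_center}"
            f" +/- {self.model.window.half_width} deg,"
            f" psi {self.model.window.psi_center}"
            f" +/- {self.model.window.half_width} deg",
            "",
            f"  {'segment':<10}{'content(obs)':>14}{'content(chain)':>16}{'n_obs':>10}",
        ]
        for name in self.segment_names():
            sub = self.windowed[self.windowed["segment"] == name]
            lines.append(
                f"  {name:<10}{self.run_summary(name, 'obs'):>14.4f}"
                f"{self.run_summary(name, 'chain'):>16.4f}"
                f"{int(sub['n_obs'].sum()):>10}"
            )
        if self.per_repeat is not None:
            lines.append("")
            lines.append(f"  {'repeat':<10}{'content(obs)':>14}{'n_obs':>10}")
            for name in self.per_repeat["segment"].unique():
                sub = self.per_repeat[self.per_repeat["segment"] == name]
                frac = (sub["fraction"] * sub["n_obs"]).sum() / sub["n_obs"].sum()
                lines.append(
                    f"  {name:<10}{frac:>14.4f}{int(sub['n_obs'].sum()):>10}"
                )
        return "\n".join(lines)

    def plot_windowed(self, segment_name: str, ax=None):
        """Windowed content traces, one line per chain (Fig-3b/3c style)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.windowed[self.windowed["segment"] == segment_name]
        for chain, d in sub.groupby("chain"):
            ax.plot(d["time_ns"], d["fraction"], marker="o", label=str(chain))
        ax.set_xlabel("time (ns)")
        ax.set_ylabel("PPII fraction")
        ax.set_title(f"PPII content, segment {segment_name}")
        ax.set_ylim(0, 1)
        ax.legend(fontsize="small")
        return ax

    def plot_per_residue(self, chain: str, ax=None):
        """Mean per-residue PPII population bars (Fig-3e style)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.per_residue[self.per_residue["chain"] == chain]
        ax.bar(sub["residue_index"], sub["mean_fraction"])
        ax.set_xlabel("residue")
        ax.set_ylabel("mean PPII population")
        ax.set_title(f"chain {chain}")
        ax.set_ylim(0, 1)
        return ax
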