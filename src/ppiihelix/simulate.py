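"""Synthetic inputs for every stage of the PPII analysis.

This module generates, with full reproducibility from a single seed:

* ideal-geometry peptide backbones at prescribed (phi, psi) — the
  round-trip oracle for the dihedral code and a source of multi-model PDB
  input;
* two-state dihedral ensembles in which every residue switches between a
  PPII state (angles uniform inside the classification window) and a coil
  state (angles uniform outside it) with a known stationary occupancy —
  the trajectory estimators must recover that occupancy;
* far-UV CD spectrum series built as a linear two-state mixture of a PPII
  basis spectrum and a coil basis spectrum with a population linear in
  temperature, plus the melt trace at 217 nm;
* near-coil chemical-shift tables with couplings in the 5.5-8.0 Hz band.

The default simulation mirrors the experimental system: seven independent
chains carrying the Gly/Met-rich C-terminal stretch AGGMGGMGGMGGMM, with
per-residue PPII occupancies in the 15-40% regime.

The generator reproduces the statistical structure the analysis assumes —
exact two-state kinetics, classification-disjoint states, noiseless linear
mixtures — and none of the physics (no solvent, no energetics, no chain
interactions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cd import CDSpectrum, MeltTrace, PPII_ZERO_MRE, PPII_RANGE_MRE
from .geometry import BackboneCoordinates, DihedralPair, PPIIWindow
from .nmr import coil_reference, make_shift_table
from .trajectory import GROEL_CTC, GROEL_CTS, DihedralEnsemble, one_to_three

__all__ = [
    "GeometryParams",
    "SimulationSpec",
    "CDBasis",
    "build_backbone",
    "simulate_ensemble",
    "simulate_cd_series",
    "simulate_shift_table",
    "default_cd_basis",
]


@dataclass(frozen=True)
class GeometryParams:
    """Ideal peptide-backbone internal coordinates (Engh-Huber-like values).

    Bond lengths in Angstrom, bond angles in degrees; the peptide bond is
    held trans (omega = 180 deg).
    """

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    angle_n_ca_c: float = 111.0
    angle_ca_c_n: float = 116.6
    angle_c_n_ca: float = 121.7
    omega: float = 180.0

    def __post_init__(self) -> None:
        for name in ("bond_n_ca", "bond_ca_c", "bond_c_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("angle_n_ca_c", "angle_ca_c_n", "angle_c_n_ca"):
            if not 0.0 < getattr(self, name) < 180.0:
                raise ValueError(f"{name} must lie in (0, 180) deg")


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D so that |CD| = bond, angle(B,C,D) = angle and the
    torsion A-B-C-D equals torsion_deg (natural extension reference frame)."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("cannot place atom: reference atoms are collinear")
    n = n / nn
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    sequence: str,
    dihedrals: list[DihedralPair],
    params: GeometryParams | None = None,
    chain_id: str = "A",
    model_index: int = 0,
) -> BackboneCoordinates:
    """Grow an N/CA/C backbone at the given (phi, psi) with ideal geometry.

    ``dihedrals[i]`` supplies residue i's angles; the first residue's phi
    and the last residue's psi are never used and may be NaN.  The first
    residue is placed in a canonical frame (N at the origin, CA on +x, C in
    the xy plane), so two builds of the same angles are identical.
    """
    g = params if params is not None else GeometryParams()
    nres = len(sequence)
    if len(dihedrals) != nres:
        raise ValueError(
            f"got {len(dihedrals)} dihedral pairs for {nres} residues"
        )
    if nres < 1:
        raise ValueError("sequence is empty")

    n = np.zeros((nres, 3))
    ca = np.zeros((nres, 3))
    c = np.zeros((nres, 3))

    # canonical frame for residue 1
    n[0] = (0.0, 0.0, 0.0)
    ca[0] = (g.bond_n_ca, 0.0, 0.0)
    ang = math.radians(g.angle_n_ca_c)
    c[0] = ca[0] + g.bond_ca_c * np.array([-math.cos(ang), math.sin(ang), 0.0])

    for i in range(1, nres):
        psi_prev = dihedrals[i - 1].psi
        phi_i = dihedrals[i].phi
        if math.isnan(psi_prev):
            raise ValueError(f"psi of residue {i} is undefined but needed for the build")
        if math.isnan(phi_i):
            raise ValueError(f"phi of residue {i + 1} is undefined but needed for the build")
        n[i] = _place_atom(n[i - 1], ca[i - 1], c[i - 1], g.bond_c_n, g.angle_ca_c_n, psi_prev)
        ca[i] = _place_atom(ca[i - 1], c[i - 1], n[i], g.bond_n_ca, g.angle_c_n_ca, g.omega)
        c[i] = _place_atom(c[i - 1], n[i], ca[i], g.bond_ca_c, g.angle_n_ca_c, phi_i)

    return BackboneCoordinates(
        chain_id=chain_id,
        residue_names=[one_to_three(aa) for aa in sequence],
        n=n,
        ca=ca,
        c=c,
        model_index=model_index,
    )


@dataclass
class SimulationSpec:
    """Conditions for a two-state dihedral ensemble.

    ``occupancy`` is the stationary per-residue PPII probability (scalar or
    one value per residue); ``persistence`` scales both states' mean dwell
    times (in frames): 1 means frames are independent draws, larger values
    add temporal autocorrelation with mean PPII dwell
    persistence / (1 - occupancy) and mean coil dwell
    persistence / occupancy.
    """

    n_chains: int = 7
    sequence: str = GROEL_CTS
    n_frames: int = 1000
    dt_ns: float = 1.0
    occupancy: float | np.ndarray = 0.25
    persistence: float = 1.0
    seed: int = 0
    window: PPIIWindow = field(default_factory=PPIIWindow)

    def occupancy_profile(self) -> np.ndarray:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim == 0:
            occ = np.full(len(self.sequence), float(occ))
        if occ.shape != (len(self.sequence),):
            raise ValueError(
                f"occupancy has shape {occ.shape}, expected scalar or ({len(self.sequence)},)"
            )
        if np.any(occ < 0.0) or np.any(occ > 1.0):
            raise ValueError("occupancy values must lie in [0, 1]")
        return occ

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_frames < 1:
            raise ValueError("n_chains and n_frames must be positive")
        if self.persistence < 1.0:
            raise ValueError("persistence must be >= 1 frame")
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be positive")
        self.occupancy_profile()  # validate eagerly


def _sample_states(rng: np.random.Generator, p: float, kappa: float, n: int) -> np.ndarray:
    """Two-state Markov chain started from its stationary distribution.

    Per-frame switching probabilities (1-p)/kappa out of the PPII state and
    p/kappa out of the coil state keep the stationary occupancy exactly p
    for any persistence kappa >= 1 and reduce to iid Bernoulli(p) draws at
    kappa = 1.
    """
    if p <= 0.0:
        return np.zeros(n, dtype=bool)
    if p >= 1.0:
        return np.ones(n, dtype=bool)
    leave_ppii = (1.0 - p) / kappa
    leave_coil = p / kappa
    u = rng.random(n)
    states = np.empty(n, dtype=bool)
    states[0] = u[0] < p
    for t in range(1, n):
        if states[t - 1]:
            states[t] = u[t] >= leave_ppii
        else:
            states[t] = u[t] < leave_coil
    return states


def _sample_ppii_angles(rng: np.random.Generator, w: PPIIWindow, n: int):
    phi = rng.uniform(w.phi_center - w.half_width, w.phi_center + w.half_width, n)
    psi = rng.uniform(w.psi_center - w.half_width, w.psi_center + w.half_width, n)
    return phi, psi


def _sample_coil_angles(rng: np.random.Generator, w: PPIIWindow, n: int):
    """Uniform on the (phi, psi) torus excluding the window, by rejection."""
    phi = np.empty(n)
    psi = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        cand_phi = rng.uniform(-180.0, 180.0, remaining.size)
        cand_psi = rng.uniform(-180.0, 180.0, remaining.size)
        inside = np.asarray(w.contains(cand_phi, cand_psi))
        keep = ~inside
        phi[remaining[keep]] = cand_phi[keep]
        psi[remaining[keep]] = cand_psi[keep]
        remaining = remaining[inside]
    return phi, psi


def simulate_ensemble(spec: SimulationSpec) -> DihedralEnsemble:
    """Draw a two-state dihedral ensemble with known PPII occupancy.

    Each (chain, residue) evolves as an independent two-state Markov chain;
    in the PPII state angles are uniform strictly inside the classification
    window (so nominal and classifiable occupancy coincide exactly), in the
    coil state uniform outside it.  Chain termini carry NaN for the
    undefined phi (first residue) and psi (last residue), as measured
    chains do.  The single seed expands deterministically into one
    substream per (chain, residue) via numpy SeedSequence spawning, so
    identical specs give bit-identical ensembles.
    """
    occ = spec.occupancy_profile()
    nres = len(spec.sequence)
    w = spec.window
    times = np.arange(1, spec.n_frames + 1, dtype=float) * spec.dt_ns

    chains = [f"chain{k + 1}" for k in range(spec.n_chains)]
    phi: dict[str, np.ndarray] = {}
    psi: dict[str, np.ndarray] = {}
    root = np.random.SeedSequence(spec.seed)
    chain_seeds = root.spawn(spec.n_chains)
    for k, chain in enumerate(chains):
        p_arr = np.empty((spec.n_frames, nres))
        s_arr = np.empty((spec.n_frames, nres))
        res_seeds = chain_seeds[k].spawn(nres)
        for r in range(nres):
            rng = np.random.default_rng(res_seeds[r])
            states = _sample_states(rng, occ[r], spec.persistence, spec.n_frames)
            n_in = int(states.sum())
            ph = np.empty(spec.n_frames)
            ps = np.empty(spec.n_frames)
            if n_in:
                ph[states], ps[states] = _sample_ppii_angles(rng, w, n_in)
            if n_in < spec.n_frames:
                ph[~states], ps[~states] = _sample_coil_angles(rng, w, spec.n_frames - n_in)
            p_arr[:, r] = ph
            s_arr[:, r] = ps
        p_arr[:, 0] = np.nan   # first residue has no phi
        s_arr[:, -1] = np.nan  # last residue has no psi
        phi[chain], psi[chain] = p_arr, s_arr

    return DihedralEnsemble(
        chains=chains,
        times=times,
        phi=phi,
        psi=psi,
        sequence={c: spec.sequence for c in chains},
    )


# ---------------------------------------------------------------------------
# CD series

@dataclass
class CDBasis:
    """Pure-state basis spectra for the two-state CD mixture.

    ``ppii`` and ``coil`` are MRE arrays on a shared wavelength grid with
    values at 212 nm pinned to the empirical calibration endpoints (+9580
    and -5560 deg cm^2 dmol^-1), so the mixture's maximum inverts exactly
    through the population equation.
    """

    wavelengths: np.ndarray
    ppii: np.ndarray
    coil: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ppii = np.asarray(self.ppii, dtype=float)
        self.coil = np.asarray(self.coil, dtype=float)
        if not (self.wavelengths.shape == self.ppii.shape == self.coil.shape):
            raise ValueError("basis arrays must share one wavelength grid")


def default_cd_basis() -> CDBasis:
    """Gaussian-band basis spectra on a 205-260 nm grid (1 nm steps).

    The PPII basis has the characteristic positive band at 212 nm and a
    deep-UV negative band centred at 195 nm; the coil basis is negative at
    212 nm with a slightly weaker deep-UV band.  The 212 nm amplitudes are
    pinned exactly to +9580 / -5560 deg cm^2 dmol^-1, the 100% and 0%
    endpoints of the empirical population calibration.  The deep-UV band
    sits mostly below the grid edge, which keeps temperature difference
    spectra proportional to the PPII basis over the analysed window.
    """
    wl = np.arange(205.0, 261.0, 1.0)
    band212 = np.exp(-(((wl - 212.0) / 9.0) ** 2))
    deep_uv = np.exp(-(((wl - 195.0) / 5.0) ** 2))
    i212 = int(np.where(wl == 212.0)[0][0])

    ppii = (PPII_ZERO_MRE + PPII_RANGE_MRE) * band212 - 16000.0 * deep_uv
    ppii += ((PPII_ZERO_MRE + PPII_RANGE_MRE) - ppii[i212]) * band212
    coil = PPII_ZERO_MRE * band212 - 15000.0 * deep_uv
    coil += (PPII_ZERO_MRE - coil[i212]) * band212
    return CDBasis(wavelengths=wl, ppii=ppii, coil=coil)


def simulate_cd_series(
    pop0: float = 43.3,
    slope_pop: float = -0.09,
    temps=None,
    basis: CDBasis | None = None,
    melt_wavelength: float = 217.0,
) -> tuple[list[CDSpectrum], MeltTrace]:
    """CD spectra and melt trace for a PPII population linear in temperature.

    spectrum(T) = p(T) * basis_ppii + (1 - p(T)) * basis_coil with
    p(T) = (pop0 + slope_pop * T) / 100.  Defaults give a 43.3% population
    at 0 C decaying by 0.09 %/C, the non-cooperative melt regime of the
    Gly/Met-rich peptides.  Populations must stay within [0, 100] over the
    requested temperatures.
    """
    temps = np.asarray(
        temps if temps is not None else np.arange(0.0, 66.0, 5.0), dtype=float
    )
    b = basis if basis is not None else default_cd_basis()
    pops = pop0 + slope_pop * temps
    if np.any(pops < 0.0) or np.any(pops > 100.0):
        raise ValueError("population leaves [0, 100] % over the requested temperatures")

    if melt_wavelength not in b.wavelengths:
        raise ValueError(f"melt wavelength {melt_wavelength} nm not on the basis grid")
    i_melt = int(np.where(b.wavelengths == melt_wavelength)[0][0])

    spectra = []
    melt_vals = []
    for T, pop in zip(temps, pops):
        p = pop / 100.0
        mre = p * b.ppii + (1.0 - p) * b.coil
        spectra.append(
            CDSpectrum(
                wavelengths=b.wavelengths.copy(),
                mre=mre,
                temperature=float(T),
                label=f"{T:g}C",
            )
        )
        melt_vals.append(mre[i_melt])
    melt = MeltTrace(
        temperatures=temps,
        mre=np.asarray(melt_vals),
        wavelength=melt_wavelength,
    )
    return spectra, melt


def simulate_shift_table(
    sequence: str = GROEL_CTS,
    dca_scale: float = 0.2,
    seed: int = 0,
    temperature: float = 25.0,
):
    """Near-coil chemical-shift table with couplings in the coil/PPII band.

    Observed 13C-alpha shifts are the packaged coil references plus uniform
    noise in +/- dca_scale ppm (1H-alpha noise is a tenth of that);
    couplings are uniform in [5.5, 8.0] Hz.  dca_scale = 0 reproduces the
    references exactly.
    """
    if dca_scale < 0:
        raise ValueError("dca_scale must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ref = coil_reference(sequence, temperature)
    n = len(sequence)
    ca_obs = ref["ca_ref_ppm"].to_numpy() + rng.uniform(-dca_scale, dca_scale, n)
    ha_obs = ref["ha_ref_ppm"].to_numpy() + rng.uniform(-dca_scale / 10, dca_scale / 10, n)
    j = rng.uniform(5.5, 8.0, n)
    return make_shift_table(
        sequence, ca_obs=ca_obs, j_hnha=j, ha_obs=ha_obs, temperature=temperature
    )
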