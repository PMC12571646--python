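# ppiihelix

Quantify **polyproline II (PPII) helix** content in disordered peptide
segments — such as the Gly/Met-rich C-terminal tails of the chaperonins
GroEL, mHsp60 and Cpn60 — from three independent evidence streams:

1. **Conformational ensembles** (MD-style multi-model PDB or per-frame
   φ/ψ tables): a residue in a frame counts as PPII when its backbone
   dihedrals fall in the window φ = −75° ± 20°, ψ = +150° ± 20°
   (circular distance, boundaries inclusive).  The package aggregates the
   per-frame indicator into trailing-window content traces (default 50 ns
   windows), per-GGM-repeat content pooled over chains, whole-run
   per-residue populations, and a single observation-weighted content
   scalar per segment, always recording the denominator of defined
   (φ, ψ) observations.
2. **Far-UV circular dichroism**: the PPII population follows from the
   empirical calibration
   `%PPII = 100 ([Θ]max + 5560) / 15140`,
   with [Θ]max the maximum mean residue ellipticity (deg·cm²·dmol⁻¹)
   sampled between 210 and 230 nm.  Thermal melts at a fixed wavelength
   (217 nm by convention) are fit by ordinary least squares; a linear,
   non-cooperative signal loss — checked by a correlation threshold plus a
   residual-sign runs test — is the PPII→coil signature.  Temperature
   difference spectra isolate the melting species' band shape.
3. **NMR**: conformational chemical shifts Δδ¹³Cα = δ_obs − δ_coil against
   a packaged random-coil reference table, combined with ³J(HN–Hα)
   couplings.  Near-zero Δδ with J in 5.5–8.0 Hz is consistent with coil
   *or* PPII (NMR cannot separate the two at residue level — CD carries
   that distinction); large positive Δδ with small J flags α-helix, large
   negative Δδ with large J flags β-strand.

A synthetic-data module generates every input with known ground truth:
ideal-geometry backbones at prescribed (φ, ψ), two-state Markov dihedral
ensembles with exact stationary PPII occupancy, linear two-state CD
mixtures, and near-coil shift tables — so the whole pipeline is testable
without a microsecond MD run or a spectrometer.

## Worked example

```python
from ppiihelix import (SimulationSpec, simulate_ensemble, TrajectoryPPII,
                       simulate_cd_series, CDMelt, theta_max, ppii_population)

# seven chains of the GroEL CtS segment at 22% PPII occupancy, 1 us at 1 ns/frame
ens = simulate_ensemble(SimulationSpec(n_chains=7, n_frames=1000,
                                       occupancy=0.22, seed=42))
print(TrajectoryPPII(ens).fit().summary())
```

```
PPII content summary
  frames: 1000  chains: 7  window: 50.0 ns / stride 50.0 ns
  classification window: phi -75.0 +/- 20.0 deg, psi 150.0 +/- 20.0 deg

  segment     content(obs)  content(chain)     n_obs
  CtC               0.2215          0.2215     84000
  CtS               0.2215          0.2215     84000

  repeat      content(obs)     n_obs
  GGM1              0.2246     21000
  GGM2              0.2218     21000
  GGM3              0.2191     21000
  GGM4              0.2204     21000
```

The estimator recovers the 22% ground-truth occupancy from 84 000
defined-dihedral observations, and no GGM repeat is preferred — exactly
the exchangeability a uniform simulation should show.  The CD branch:

```python
spectra, melt = simulate_cd_series(pop0=43.3, slope_pop=-0.09)
wl, th = theta_max(spectra[0])        # (212.0, 996) at 0 C
print(ppii_population(th))            # 43.3
print(CDMelt(melt).fit().summary())
```

```
CD thermal melt fit (OLS)
  wavelength: 217 nm   points: 14   T range: 0-65 C
  [theta] = 731.335 -10.0075 * T(C)   R = -1.0000
  stderr: intercept 0, slope 0
  linear (non-cooperative): True  (runs-test p = 1, longest sign run = 0)
```

A maximum ellipticity of ~1000 deg·cm²·dmol⁻¹ maps to a 43% PPII
population, and the 217 nm melt is perfectly linear by construction —
the behaviour real Gly/Met-rich tails show.

## Command line

```sh
ppii sim traj --seed 7 --out sim/         # synthetic dihedral TSV
ppii traj --input sim/dihedrals.tsv --out traj/
ppii cd --spectra spectra.csv --melt melt.csv --out cd/
ppii nmr --shifts shifts.tsv --out nmr/
```

Each run writes plain TSV/CSV/JSON results plus a `manifest.json` with
every parameter, the package version and the seed; logs go to stderr.

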