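import numpy as np
import pytest

from ppiihelix import DihedralEnsemble, PPIIWindow


@pytest.fixture
def default_window() -> PPIIWindow:
    return PPIIWindow()


def constant_ensemble(
    phi: float,
    psi: float,
    n_frames: int = 10,
    sequence: str = "AGGMGGMGGMGGMM",
    chains=("chain1",),
    dt_ns: float = 1.0,
    nan_termini: bool = True,
) -> DihedralEnsemble:
    """Every residue of every frame at the same (phi, psi)."""
    nres = len(sequence)
    times = np.arange(1, n_frames + 1, dtype=float) * dt_ns
    phi_d, psi_d = {}, {}
    for c in chains:
        p = np.full((n_frames, nres), float(phi))
        s = np.full((n_frames, nres), float(psi))
        if nan_termini:
            p[:, 0] = np.nan
            s[:, -1] = np.nan
        phi_d[c], psi_d[c] = p, s
    return DihedralEnsemble(
        chains=list(chains),
        times=times,
        phi=phi_d,
        psi=psi_d,
        sequence={c: sequence for c in chains},
    )


@pytest.fixture
def make_constant_ensemble():
    return constant_ensemble
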