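"""One-call computation of the 13 reported HRV indices for a segment."""

from __future__ import annotations

from dataclasses import asdict, dataclass

from . import frequency, nonlinear, time_domain

#: Column order used in all tabular output.
INDEX_NAMES = [
    "mean_rr",
    "sdnn",
    "mean_hr",
    "rmssd",
    "rr_tri",
    "lf_nu",
    "hf_nu",
    "lf_ms2",
    "hf_ms2",
    "apen",
    "sampen",
    "dfa_a1",
    "dfa_a2",
]

#: Human-readable labels matching the reporting convention of the field.
INDEX_LABELS = {
    "mean_rr": "Mean RR (ms)",
    "sdnn": "SDNN (ms)",
    "mean_hr": "Mean HR (bpm)",
    "rmssd": "RMSSD (ms)",
    "rr_tri": "RR Tri",
    "lf_nu": "LF (n.u.)",
    "hf_nu": "HF (n.u.)",
    "lf_ms2": "LF (ms^2)",
    "hf_ms2": "HF (ms^2)",
    "apen": "ApEn",
    "sampen": "SampEn",
    "dfa_a1": "DFA a1",
    "dfa_a2": "DFA a2",
}


@dataclass
class HRVIndices:
    mean_rr: float
    sdnn: float
    mean_hr: float
    rmssd: float
    rr_tri: float
    lf_nu: float
    hf_nu: float
    lf_ms2: float
    hf_ms2: float
    apen: float
    sampen: float
    dfa_a1: float
    dfa_a2: float

    def as_dict(self) -> dict:
        return asdict(self)


def compute_indices(
    window,
    entropy_settings: nonlinear.EntropySettings = nonlinear.EntropySettings(),
    dfa_settings: nonlinear.DFASettings = nonlinear.DFASettings(),
) -> HRVIndices:
    """Compute all time, frequency and nonlinear indices for one window."""
    spec = frequency.spectral_indices(window)
    a1, a2 = nonlinear.dfa(window, dfa_settings)
    return HRVIndices(
        mean_rr=time_domain.mean_rr(window),
        sdnn=time_domain.sdnn(window),
        mean_hr=time_domain.mean_hr(window),
        rmssd=time_domain.rmssd(window),
        rr_tri=time_domain.rr_tri(window),
        lf_nu=spec["lf_nu"],
        hf_nu=spec["hf_nu"],
        lf_ms2=spec["lf_ms2"],
        hf_ms2=spec["hf_ms2"],
        apen=nonlinear.apen(window, entropy_settings),
        sampen=nonlinear.sampen(window, entropy_settings),
        dfa_a1=a1,
        dfa_a2=a2,
    )
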