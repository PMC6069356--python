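"""Seeded generators for synthetic assay data and test corpora.

All generators are pure functions of their parameters and seed. The
calibration generator reproduces the assay's log-linear signal law with
homoscedastic Gaussian replicate noise — the error bars of a triplicate
fluorescence calibration are symmetric and roughly constant, and nothing
richer is identifiable from endpoint readouts. Serum backgrounds are
emulated as a positive offset on the blank (potassium-driven quadruplex
background), leaving the noise scale untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import ReadoutTable
from .strands import NucleotideStrand, OligoPanel, reverse_complement

__all__ = [
    "CalibrationDesign",
    "generate_calibration_readouts",
    "generate_blank_readouts",
    "random_hairpin_panel",
]

#: Thrombin calibration series (nM); 0 is the blank.
DEFAULT_SERIES_NM = (0.0, 0.01, 0.05, 0.1, 0.5, 1.0, 10.0, 50.0)


@dataclass(frozen=True)
class CalibrationDesign:
    """Design of a synthetic calibration experiment.

    Defaults follow the assay as run: the 0-50 nM series with triplicate
    readings, the published calibration coefficients as the generating
    line, and a replicate noise of 50 signal units. The blank mean sits
    half a decade below the lowest calibrator's expected signal.
    """

    concentrations_nM: tuple[float, ...] = DEFAULT_SERIES_NM
    replicates: int = 3
    slope: float = 721.64
    intercept: float = 3432.27
    sigma: float = 50.0
    blank_mean: float | None = None
    seed: int = 0
    channel: str = "fluorescence"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.sigma < 0:
            raise ValueError("noise sd must be >= 0")

    @property
    def effective_blank_mean(self) -> float:
        if self.blank_mean is not None:
            return self.blank_mean
        positives = [c for c in self.concentrations_nM if c > 0]
        x_low = min(positives) if positives else 1.0
        return self.intercept + self.slope * (np.log10(x_low) - 0.5)


def generate_calibration_readouts(design: CalibrationDesign) -> ReadoutTable:
    """Draw a replicate readout table from the design's signal law.

    Y = slope * lg X + intercept + N(0, sigma^2) for X > 0; blanks are
    drawn around the design's blank mean with the same noise.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for conc in design.concentrations_nM:
        if conc > 0:
            mean = design.slope * np.log10(conc) + design.intercept
        else:
            mean = design.effective_blank_mean
        for rep in range(1, design.replicates + 1):
            noise = rng.normal(0.0, design.sigma) if design.sigma > 0 else 0.0
            rows.append(
                {
                    "concentration_nM": conc,
                    "replicate": rep,
                    "signal": mean + noise,
                    "channel": design.channel,
                }
            )
    return ReadoutTable(pd.DataFrame(rows))


def generate_blank_readouts(
    mean: float,
    sigma: float,
    n: int,
    seed: int = 0,
    serum_offset: float = 0.0,
) -> np.ndarray:
    """n seeded Gaussian blank readings, optionally with a serum background.

    ``serum_offset`` shifts the mean upward (elevated background in serum)
    without changing the spread.
    """
    if n < 2:
        raise ValueError("need n >= 2 blank readings")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    return mean + serum_offset + rng.normal(0.0, sigma, size=n)


def random_hairpin_panel(
    stem_len: int,
    loop_len: int,
    count: int,
    seed: int = 0,
) -> OligoPanel:
    """Random designed hairpins: stem + loop + reverse complement of stem.

    Useful as a corpus whose intended fold is known by construction. Loops
    shorter than 3 cannot close a hairpin and are rejected.
    """
    if stem_len < 1:
        raise ValueError("stem_len must be >= 1")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    panel = OligoPanel()
    for i in range(count):
        stem = "".join(rng.choice(bases, size=stem_len))
        loop = "".join(rng.choice(bases, size=loop_len))
        stem_rc = reverse_complement(NucleotideStrand("tmp", stem)).bases
        panel.add(NucleotideStrand(f"hairpin_{i + 1}", stem + loop + stem_rc))
    return panel
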