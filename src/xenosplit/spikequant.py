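"""Spike-in mass bookkeeping and absolute exRNA quantification.

A spike panel lists each synthetic RNA's length (nt) and stock molar
concentration (attomol/ul).  The mass added per sample follows from
concentration x volume x dilution (attomol -> mol) x length x the average
nucleotide weight (321.47 g/mol); panel masses sum to the per-sample spike
mass, which over the plasma input volume gives pg spike per mL.  Endogenous
concentration then scales that per-mL mass by the endogenous/spike read-count
ratio, and the tumour fraction is the human share of the two concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

#: average molecular weight of a single RNA nucleotide, g/mol
NT_MOLECULAR_WEIGHT = 321.47
ATTO = 1e-18


@dataclass(frozen=True)
class SpikeDefinition:
    spike_id: str
    length_nt: int
    attomol_per_ul: float

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValueError(f"{self.spike_id}: length must be positive")
        if self.attomol_per_ul < 0:
            raise ValueError(f"{self.spike_id}: concentration must be non-negative")


@dataclass(frozen=True)
class SpikeProtocol:
    """Volumes and dilutions of the spiking protocol.

    Defaults follow the 2 ul spike addition at 1/10,000 dilution with a
    60 ul plasma input; platelet lysates prepared from 70 ul plasma use
    ``input_volume_ml=0.070``.
    """

    volume_added_ul: float = 2.0
    dilution_factor: float = 1e-4
    nt_molecular_weight: float = NT_MOLECULAR_WEIGHT
    input_volume_ml: float = 0.060

    def __post_init__(self) -> None:
        for name in ("volume_added_ul", "dilution_factor", "nt_molecular_weight", "input_volume_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"protocol field {name} must be positive")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SpikeProtocol":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def read_spike_panel(path: Union[str, Path]) -> list[SpikeDefinition]:
    """Panel TSV with columns spike_id, length_nt, attomol_per_ul."""
    df = pd.read_csv(path, sep="\t")
    required = {"spike_id", "length_nt", "attomol_per_ul"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        SpikeDefinition(str(r.spike_id), int(r.length_nt), float(r.attomol_per_ul))
        for r in df.itertuples()
    ]


def spike_mass(spike: SpikeDefinition, proto: SpikeProtocol) -> float:
    """Grams of one spike added to the sample."""
    mol = spike.attomol_per_ul * proto.volume_added_ul * proto.dilution_factor * ATTO
    return mol * spike.length_nt * proto.nt_molecular_weight


def panel_total_mass(panel: Sequence[SpikeDefinition], proto: SpikeProtocol) -> float:
    """Total grams of spike added per sample: sum of per-spike masses."""
    if not panel:
        raise ValueError("spike panel is empty")
    return sum(spike_mass(s, proto) for s in panel)


def mass_per_ml(total_mass_g: float, input_volume_ml: float) -> float:
    """pg of spike per mL of input material."""
    if input_volume_ml <= 0:
        raise ValueError("input volume must be positive")
    return total_mass_g * 1e12 / input_volume_ml


def endogenous_concentration(
    endo_counts: float, sequin_counts: float, spike_mass_per_ml: float
) -> float:
    """pg/mL of endogenous RNA from the endogenous/Sequin read-count ratio."""
    if sequin_counts <= 0:
        raise ValueError("sequin count is zero; quantification impossible")
    return (endo_counts / sequin_counts) * spike_mass_per_ml


def tumour_fraction(conc_human: float, conc_mouse: float) -> Optional[float]:
    """Percent of total exRNA that is human (tumour); None when both are zero."""
    total = conc_human + conc_mouse
    if total <= 0:
        return None
    return 100.0 * conc_human / total


@dataclass
class SampleQuantification:
    sample_id: str
    human_counts: int
    mouse_counts: int
    sequin_counts: int
    conc_human_pg_per_ml: float
    conc_mouse_pg_per_ml: float
    tumour_fraction_pct: Optional[float]


def quantify_sample(
    sample_id: str,
    human_counts: int,
    mouse_counts: int,
    sequin_counts: int,
    panel: Sequence[SpikeDefinition],
    proto: SpikeProtocol,
) -> SampleQuantification:
    per_ml = mass_per_ml(panel_total_mass(panel, proto), proto.input_volume_ml)
    ch = endogenous_concentration(human_counts, sequin_counts, per_ml)
    cm = endogenous_concentration(mouse_counts, sequin_counts, per_ml)
    return SampleQuantification(
        sample_id=sample_id,
        human_counts=human_counts,
        mouse_counts=mouse_counts,
        sequin_counts=sequin_counts,
        conc_human_pg_per_ml=ch,
        conc_mouse_pg_per_ml=cm,
        tumour_fraction_pct=tumour_fraction(ch, cm),
    )


def quantification_table(quants: Sequence[SampleQuantification]) -> pd.DataFrame:
    rows = []
    for q in quants:
        rows.append(
            {
                "sample_id": q.sample_id,
                "human_counts": q.human_counts,
                "mouse_counts": q.mouse_counts,
                "sequin_counts": q.sequin_counts,
                "conc_human_pg_per_ml": q.conc_human_pg_per_ml,
                "conc_mouse_pg_per_ml": q.conc_mouse_pg_per_ml,
                "tumour_fraction_pct": q.tumour_fraction_pct,
            }
        )
    return pd.DataFrame(rows)


def sequin_ercc_ratio(sequin_counts: int, ercc_counts: int) -> Optional[float]:
    """QC metric: Sequin/ERCC read-count ratio (ERCC is a process control)."""
    if ercc_counts <= 0:
        return None
    return sequin_counts / ercc_counts
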