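"""Synthetic instrument data with known ground truth.

Every input the analysis pipeline consumes can be generated here with
planted parameters, so each stage is testable end to end without any
patient material or instrument access:

* protease substrate windows drawn from a planted specificity motif over a
  proteome-like background, plus a parent sequence carrying fragments
  whose termini coincide with planted cleavage sites (the fibril-fragment
  analysis scenario);
* nanoDSF melt curves (I330/I350 vs temperature across a urea grid)
  produced by the exact forward model that the global unfolding fit
  inverts;
* DLS cumulant-radius traces with a known aggregation onset;
* ThT aggregation traces from the sigmoid kinetics equation.

All randomness flows from a single integer seed; identical configuration
gives bit-identical outputs.  Noise is i.i.d. Gaussian throughout — the
simplest model that supports parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import aggkin, foldfit
from .aggkin import SigmoidalFit, ThtTrace
from .cleavage import (
    AMINO_ACIDS,
    WINDOW_LENGTH,
    CleavageWindow,
    PeptideFragment,
    background_vector,
)
from .foldfit import StabilityParams
from .thermostab import DlsTrace, MeltCurve, TurbidityTrace

__all__ = [
    "SynthConfig",
    "CleavageDataset",
    "DEFAULT_MOTIFS",
    "default_stability_truth",
    "PAPER_UREA_GRID",
    "gen_cleavage_dataset",
    "gen_melt_curves",
    "gen_dls_trace",
    "gen_turbidity_trace",
    "gen_tht_trace",
    "write_fasta",
    "write_windows_tsv",
    "write_fragments_tsv",
    "write_melt_curves_csv",
    "read_melt_curves_csv",
    "write_truth_json",
]

#: Urea grid of the standard chemical-denaturation protocol (molar).
PAPER_UREA_GRID = (0.0, 0.67, 1.34, 2.01, 2.68, 3.35, 4.02, 4.69, 5.36)

# Motif = {window position (0..7, i.e. P4..P4') -> {residue -> probability}}.
# Remaining probability mass at a motif position falls back to background.
Motif = Mapping[int, Mapping[str, float]]

#: Cathepsin-like default motifs: the cysteine protease prefers bulky
#: hydrophobics at P2 and basic residues at P1; the aspartyl protease
#: prefers hydrophobics on both sides of the scissile bond.
DEFAULT_MOTIFS: dict[str, Motif] = {
    "cathepsin_B": {2: {"L": 0.4, "F": 0.25}, 3: {"R": 0.35, "K": 0.3}},
    "cathepsin_D": {3: {"F": 0.4, "L": 0.3}, 4: {"F": 0.3, "L": 0.3}},
}


@dataclass
class SynthConfig:
    """Configuration of the synthetic-data generators.

    Defaults mirror the study's conditions: roughly 200 curated substrate
    windows per protease, a 214-residue kappa-light-chain-like parent
    sequence, and noise levels typical of plate readers and microcapillary
    instruments (a fraction of a percent of the signal for fluorescence,
    ~0.15 nm on a small-protein radius, ~2 percent of the ThT amplitude).
    """

    seed: int = 0
    n_substrates: int = 200
    motif: Mapping[str, Motif] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    background: np.ndarray | Mapping[str, float] | None = None
    noise_sd_fluor: float = 0.003
    noise_sd_radius: float = 0.15
    noise_sd_tht: float = 0.1

    def __post_init__(self) -> None:
        self.background = background_vector(self.background)
        for pid, motif in self.motif.items():
            for pos, prefs in motif.items():
                if not (0 <= int(pos) < WINDOW_LENGTH):
                    raise ValueError(
                        f"motif position {pos} for {pid} outside the "
                        f"{WINDOW_LENGTH}-residue window"
                    )
                total = sum(prefs.values())
                if total > 1.0 + 1e-9 or any(p < 0 for p in prefs.values()):
                    raise ValueError(
                        f"motif probabilities at position {pos} for {pid} "
                        "must be non-negative and sum to at most 1"
                    )
                bad = set(prefs) - set(AMINO_ACIDS)
                if bad:
                    raise ValueError(f"non-canonical motif residues: {sorted(bad)}")


@dataclass
class CleavageDataset:
    """Synthetic substrate windows, parent sequence and observed fragments."""

    windows: dict[str, list[CleavageWindow]]
    sequence: str
    fragments: list[PeptideFragment]
    true_cut_sites: list[int]  # 1-based P1 positions of planted cleavage sites
    parent_id: str = "synthetic_LC"


def _sample_window(rng: np.random.Generator, motif: Motif, bg: np.ndarray) -> str:
    chars = []
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    for j in range(WINDOW_LENGTH):
        prefs = motif.get(j)
        if prefs:
            residues = list(prefs)
            probs = list(prefs.values())
            spill = 1.0 - sum(probs)
            u = rng.random()
            acc = 0.0
            picked = None
            for r, p in zip(residues, probs):
                acc += p
                if u < acc:
                    picked = r
                    break
            if picked is None:
                picked = str(rng.choice(aa, p=bg))
            chars.append(picked)
        else:
            chars.append(str(rng.choice(aa, p=bg)))
    return "".join(chars)


def gen_cleavage_dataset(
    cfg: SynthConfig,
    seq_len: int = 214,
    n_fragments: int = 8,
) -> CleavageDataset:
    """Generate substrate windows, a parent sequence and planted fragments.

    Substrate windows per protease follow the planted motif at the motif
    positions and the background elsewhere.  The parent sequence is drawn
    from the background, then fragments are planted: each fragment's
    N-terminal cut (P1 = ``start - 1``) and C-terminal cut (P1 = ``end``)
    gets a freshly sampled motif window written into the parent at that
    site, alternating between the configured proteases.  Ground-truth cut
    positions are recorded so proximal-region construction and the edge
    enrichment test can be validated against a known answer.
    """
    if seq_len < 20:
        raise ValueError("seq_len must be at least 20")
    if n_fragments < 0:
        raise ValueError("n_fragments must be non-negative")
    rng = np.random.default_rng(cfg.seed)
    bg = cfg.background
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")

    windows = {
        pid: [
            CleavageWindow(_sample_window(rng, motif, bg), pid)
            for _ in range(cfg.n_substrates)
        ]
        for pid, motif in cfg.motif.items()
    }

    seq = list(rng.choice(aa, size=seq_len, p=bg))

    fragments: list[PeptideFragment] = []
    cut_sites: list[int] = []
    if n_fragments > 0:
        protease_ids = list(cfg.motif)
        # lay fragments on non-overlapping slots so planted windows never
        # overwrite each other; each fragment consumes two cut windows
        min_len, max_len = 12, 30
        slot = (seq_len - 2 * WINDOW_LENGTH) / n_fragments
        if slot < min_len + WINDOW_LENGTH:
            raise ValueError(
                f"cannot place {n_fragments} fragments in a {seq_len}-residue sequence"
            )
        for i in range(n_fragments):
            lo = int(WINDOW_LENGTH + i * slot)
            hi = int(WINDOW_LENGTH + (i + 1) * slot) - WINDOW_LENGTH
            length = int(rng.integers(min_len, min(max_len, hi - lo - 1) + 1))
            start = int(rng.integers(lo, hi - length + 1))
            end = start + length - 1
            fragments.append(PeptideFragment("synthetic_LC", start, end))
            for cut, pid in (
                (start - 1, protease_ids[(2 * i) % len(protease_ids)]),
                (end, protease_ids[(2 * i + 1) % len(protease_ids)]),
            ):
                if cut < 4 or cut > seq_len - 4:
                    continue  # cannot plant a full window at the margin
                win = _sample_window(rng, cfg.motif[pid], bg)
                seq[cut - 4 : cut + 4] = list(win)
                cut_sites.append(cut)

    return CleavageDataset(
        windows=windows,
        sequence="".join(seq),
        fragments=fragments,
        true_cut_sites=sorted(cut_sites),
    )


def default_stability_truth() -> StabilityParams:
    """Ground-truth unfolding parameters of a typical light chain.

    Tm of 52 deg C, a van't Hoff enthalpy of 500 kJ/mol, a heat-capacity
    change of 8 kJ/mol/K and the shared m-value of 7.1 kJ/mol/M give
    dG(37 C) of about 20 kJ/mol — squarely in the observed fingerprint
    range.  Baselines put the native state high in the 330 nm channel and
    the unfolded state high at 350 nm, as for a buried-tryptophan protein.
    """
    return StabilityParams(
        tm_C=52.0,
        dHm=500.0,
        dCp=8.0,
        m_value=7.1,
        baselines={
            330: (1.00, -0.0020, 0.65, -0.0010),
            350: (0.60, 0.0010, 0.95, 0.0005),
        },
    )


def gen_melt_curves(
    truth: StabilityParams,
    urea_grid: Sequence[float] = PAPER_UREA_GRID,
    T_grid: Sequence[float] | None = None,
    noise_sd: float = 0.003,
    n_capillaries: int = 1,
    seed: int | np.random.Generator | None = None,
    conc_uM: float = 20.0,
    sample_id: str = "synthetic_LC",
) -> list[MeltCurve]:
    """Forward-simulate nanoDSF melt curves over a urea grid.

    For each urea concentration and capillary replicate, both emission
    channels are evaluated from the two-state signal model and i.i.d.
    Gaussian noise of ``noise_sd`` (signal units) is added.  One capillary
    holds one scan at one urea concentration, mirroring the microcapillary
    format; capillary ids are unique per (urea, replicate).
    """
    T_grid = np.asarray(
        T_grid if T_grid is not None else np.arange(20.0, 70.0 + 1e-9, 1.0)
    )
    if np.any(np.diff(T_grid) <= 0):
        raise ValueError("T_grid must be strictly increasing")
    urea_grid = np.asarray(urea_grid, dtype=float)
    if np.any(urea_grid < 0):
        raise ValueError("urea concentrations must be non-negative")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    curves = []
    for iu, urea in enumerate(urea_grid):
        for rep in range(n_capillaries):
            i330 = foldfit.signal_model(truth, T_grid, urea, 330)
            i350 = foldfit.signal_model(truth, T_grid, urea, 350)
            if noise_sd > 0:
                i330 = i330 + rng.normal(0.0, noise_sd, size=len(T_grid))
                i350 = i350 + rng.normal(0.0, noise_sd, size=len(T_grid))
            curves.append(
                MeltCurve(
                    T=T_grid.copy(),
                    i330=i330,
                    i350=i350,
                    conc_uM=conc_uM,
                    urea_M=float(urea),
                    capillary_id=f"u{iu:02d}r{rep:02d}",
                    sample_id=sample_id,
                )
            )
    return curves


def gen_dls_trace(
    T_grid: Sequence[float],
    baseline_radius: float = 3.0,
    Tagg_true: float = 55.0,
    growth_amplitude: float = 500.0,
    growth_width: float = 2.0,
    noise_sd: float = 0.15,
    seed: int | np.random.Generator | None = None,
    baseline_slope: float = 0.0,
    onset_threshold: float = 0.005,
    sample_id: str = "synthetic_LC",
    conc_uM: float = 30.0,
) -> DlsTrace:
    """Simulate a cumulant-radius trace with a known aggregation onset.

    The noiseless radius is a linear baseline plus a logistic growth term.
    The logistic centre is placed so that the growth term crosses
    ``onset_threshold`` (the 0.5 percent divergence rule) of the baseline
    exactly at ``Tagg_true`` — the planted onset is then the ground truth
    the detector should recover.  ``growth_amplitude = 0`` yields a flat
    trace (plus noise).
    """
    T = np.asarray(T_grid, dtype=float)
    if baseline_radius <= 0:
        raise ValueError("baseline_radius must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    base = baseline_radius + baseline_slope * (T - T[0])
    if growth_amplitude > 0:
        target = onset_threshold * (
            baseline_radius + baseline_slope * (Tagg_true - T[0])
        )
        if target >= growth_amplitude:
            raise ValueError("growth amplitude too small for the requested onset")
        centre = Tagg_true + growth_width * np.log(growth_amplitude / target - 1.0)
        radius = base + growth_amplitude / (1.0 + np.exp(-(T - centre) / growth_width))
    else:
        radius = base.copy()
    if noise_sd > 0:
        radius = radius + rng.normal(0.0, noise_sd, size=len(T))
    return DlsTrace(T=T, radius=np.maximum(radius, 1e-3), conc_uM=conc_uM, sample_id=sample_id)


def gen_turbidity_trace(
    T_grid: Sequence[float],
    T_max: float = 66.0,
    amplitude: float = 1.0,
    width: float = 6.0,
    reversal: float = 0.8,
    noise_sd: float = 0.01,
    seed: int | np.random.Generator | None = None,
    pH: float = 5.0,
    conc_uM: float = 30.0,
) -> TurbidityTrace:
    """Simulate a heat-test turbidity scan: rise, peak near ``T_max``, partial reversal.

    ``reversal`` in [0, 1] is the fraction of the turbidity rise lost again
    by the end of the scan; ``amplitude = 0`` gives a flat (no-turbidity)
    trace.
    """
    T = np.asarray(T_grid, dtype=float)
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    # rise/fall pair whose combined maximum generally sits off the nominal
    # centre; locate the shape's true peak and translate it onto T_max
    def shape(x):
        rise = 1.0 / (1.0 + np.exp(-(x + width) / (width / 3.0)))
        fall = reversal / (1.0 + np.exp(-(x - width) / (width / 3.0)))
        return rise - fall

    fine = np.linspace(-6.0 * width, 6.0 * width, 4001)
    x_peak = fine[np.argmax(shape(fine))] if amplitude > 0 else 0.0
    y = 0.05 + amplitude * shape(T - T_max + x_peak)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(T))
    return TurbidityTrace(T=T, turbidity=y, conc_uM=conc_uM, pH=pH)


def gen_tht_trace(
    truth: SigmoidalFit,
    t_grid: Sequence[float],
    noise_sd: float = 0.1,
    seed: int | np.random.Generator | None = None,
    sample_id: str = "synthetic_LC",
    conc_uM: float = 35.0,
    pH: float = 3.0,
    replicate_id: str = "r00",
) -> ThtTrace:
    """Simulate a ThT trace from the sigmoid kinetics model plus noise."""
    t = np.asarray(t_grid, dtype=float)
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    y = aggkin.sigmoid_model(
        t, truth.y_i, truth.m_i, truth.y_f, truth.m_f, truth.t50, truth.k
    )
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(t))
    return ThtTrace(
        t=t, intensity=y, sample_id=sample_id, conc_uM=conc_uM, pH=pH,
        replicate_id=replicate_id,
    )


# ---------------------------------------------------------------------------
# plain-text serialisation (FASTA / TSV / CSV / JSON sidecar)


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_windows_tsv(path: str | Path, windows: Mapping[str, Sequence[CleavageWindow]]) -> None:
    rows = [
        {"protease": pid, "window": w.residues, "parent_id": "", "site_index": i}
        for pid, ws in windows.items()
        for i, w in enumerate(ws)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_windows_tsv(path: str | Path) -> dict[str, list[CleavageWindow]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[CleavageWindow]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["protease"]), []).append(
            CleavageWindow(str(row["window"]), str(row["protease"]))
        )
    return out


def write_fragments_tsv(path: str | Path, fragments: Sequence[PeptideFragment]) -> None:
    pd.DataFrame(
        [{"parent_id": f.parent_id, "start": f.start, "end": f.end} for f in fragments]
    ).to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path: str | Path) -> list[PeptideFragment]:
    df = pd.read_csv(path, sep="\t")
    return [
        PeptideFragment(str(r["parent_id"]), int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    ]


def write_melt_curves_csv(path: str | Path, curves: Sequence[MeltCurve]) -> None:
    """Long-format CSV: sample_id, capillary_id, urea_M, conc_uM, T_or_t, channel, value."""
    frames = []
    for c in curves:
        for channel, values in (("I330", c.i330), ("I350", c.i350)):
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": c.sample_id,
                        "capillary_id": c.capillary_id,
                        "urea_M": c.urea_M,
                        "conc_uM": c.conc_uM,
                        "T_or_t": c.T,
                        "channel": channel,
                        "value": values,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_melt_curves_csv(path: str | Path) -> list[MeltCurve]:
    df = pd.read_csv(path)
    curves = []
    for (sid, cid, urea, conc), grp in df.groupby(
        ["sample_id", "capillary_id", "urea_M", "conc_uM"], sort=True
    ):
        wide = grp.pivot_table(index="T_or_t", columns="channel", values="value")
        curves.append(
            MeltCurve(
                T=wide.index.to_numpy(dtype=float),
                i330=wide["I330"].to_numpy(dtype=float),
                i350=wide["I350"].to_numpy(dtype=float),
                conc_uM=float(conc),
                urea_M=float(urea),
                capillary_id=str(cid),
                sample_id=str(sid),
            )
        )
    return curves


def write_truth_json(path: str | Path, truth: Mapping) -> None:
    """JSON sidecar holding generator ground truth (dataclasses allowed)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"cannot serialise {type(o)}")

    Path(path).write_text(json.dumps(truth, indent=2, default=default))
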