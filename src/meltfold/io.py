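"""Readers, writers, configuration and the end-to-end pipeline.

File conventions: temperatures are °C in every file (kelvin only inside
the library); concentrations are mol/L in configs, with explicit "uM" /
"mM" suffixes accepted; spectral matrices are CSV with the wavelength in
the first column and one temperature per remaining column.
"""

from __future__ import annotations

import csv
import io as _io
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import factors, fluor, meltfit, noe, oligo, presets, synth
from .equilibria import EquilibriumConditions, ThermoParams, assoc_constant, celsius_to_kelvin
from .factors import SpectralSeries
from .fluor import FluorescencePattern, TitrationPoint
from .meltfit import ShiftProfile
from .noe import CrossPeak

__all__ = [
    "read_spectral_series",
    "write_spectral_series",
    "read_shift_profiles",
    "write_shift_profiles",
    "read_peaklist",
    "write_peaklist",
    "read_pattern_csv",
    "write_pattern_csv",
    "parse_concentration",
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_UNIT_FACTORS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "μm": 1e-6, "nm": 1e-9}


def parse_concentration(value) -> float:
    """Concentration in mol/L from a float (mol/L) or "3.08 uM"-style text."""
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([a-zA-Zµμ]+)\s*", str(value))
    if not m:
        raise ValueError(f"cannot parse concentration {value!r}")
    number, unit = m.groups()
    try:
        factor = _UNIT_FACTORS[unit.lower()]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r} in {value!r}") from None
    return float(number) * factor


# ---------------------------------------------------------------------------
# spectral series CSV: first column wavelength_nm, header temperatures in °C


def write_spectral_series(series: SpectralSeries, path) -> None:
    df = pd.DataFrame(
        series.Y.T,
        index=pd.Index(series.wavelengths, name="wavelength_nm"),
        columns=[f"{t:.6g}" for t in series.temperatures],
    )
    with open(path, "w") as fh:
        fh.write("# UV spectral series; header row = temperatures in degC\n")
        df.to_csv(fh, float_format="%.12g")


def read_spectral_series(path) -> SpectralSeries:
    rows = []
    header = None
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = (lineno, row)
                continue
            rows.append((lineno, row))
    if header is None or not rows:
        raise ValueError(f"{path}: missing header or data")
    hline, hrow = header
    if len(hrow) < 3:
        raise ValueError(f"{path}:{hline}: need a wavelength column and >= 2 temperatures")
    try:
        temps = np.array([float(x) for x in hrow[1:]])
    except ValueError:
        raise ValueError(
            f"{path}:{hline}: non-numeric temperature header {hrow[1:]!r}"
        ) from None
    if len(set(temps.tolist())) != len(temps):
        raise ValueError(f"{path}:{hline}: duplicate temperature columns")
    ncol = len(hrow)
    wl, data = [], []
    for lineno, row in rows:
        if len(row) != ncol:
            raise ValueError(f"{path}:{lineno}: ragged row ({len(row)} of {ncol} cells)")
        try:
            values = [float(x) for x in row]
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric cell in {row!r}") from None
        wl.append(values[0])
        data.append(values[1:])
    Y = np.asarray(data).T  # (n_temps, n_wavelengths)
    order = np.argsort(temps)
    return SpectralSeries(
        wavelengths=np.asarray(wl),
        temperatures=temps[order],
        Y=Y[order],
        name=str(path),
    )


# ---------------------------------------------------------------------------
# chemical-shift profile CSV: temperature_C column + one column per nucleus


def write_shift_profiles(profiles: Sequence[ShiftProfile], path) -> None:
    base = profiles[0].T
    for p in profiles:
        if len(p.T) != len(base) or np.any(p.T != base):
            raise ValueError("profiles must share one temperature grid to share a file")
    df = pd.DataFrame({"temperature_C": base})
    for p in profiles:
        df[p.nucleus] = p.delta
    with open(path, "w") as fh:
        fh.write("# chemical shifts (ppm) vs temperature (degC)\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_shift_profiles(path, sigma: float | None = None) -> list[ShiftProfile]:
    df = pd.read_csv(path, comment="#")
    if "temperature_C" not in df.columns:
        raise ValueError(f"{path}: missing temperature_C column")
    t = df["temperature_C"].to_numpy(dtype=float)
    order = np.argsort(t)
    return [
        ShiftProfile(
            nucleus=col,
            T=t[order],
            delta=df[col].to_numpy(dtype=float)[order],
            sigma=sigma,
        )
        for col in df.columns
        if col != "temperature_C"
    ]


# ---------------------------------------------------------------------------
# Sparky-style peak list

_RES = r"[ACGT]-?\d+"
_ATOM = r"M7|H\d+'{0,2}"
_ASSIGNMENT_RE = re.compile(rf"({_RES})({_ATOM})-({_RES})({_ATOM})$")


def parse_assignment(text: str) -> tuple[tuple[str, str], tuple[str, str]]:
    """Split "C-4H5-C-4H6" into (("C-4","H5"), ("C-4","H6"))."""
    m = _ASSIGNMENT_RE.fullmatch(text.strip())
    if not m:
        raise ValueError(f"malformed assignment {text!r}")
    ra, aa, rb, ab = m.groups()
    return (ra, aa), (rb, ab)


def read_peaklist(path_or_text) -> list[CrossPeak]:
    """Sparky-style list: assignment, w1 ppm, w2 ppm, volume; '#' comments.

    Negative-volume peaks are retained (flagged unusable via volume <= 0).
    Malformed lines are reported together with their line numbers.
    """
    if isinstance(path_or_text, str) and "\n" in path_or_text:
        lines = path_or_text.splitlines()
        origin = "<text>"
    else:
        lines = Path(path_or_text).read_text().splitlines()
        origin = str(path_or_text)
    peaks, errors = [], []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped or stripped.lower().startswith("assignment"):
            continue
        parts = stripped.split()
        if len(parts) < 4:
            errors.append(f"{origin}:{lineno}: expected 4 columns, got {len(parts)}")
            continue
        try:
            (atom_a, atom_b) = parse_assignment(parts[0])
            float(parts[1]), float(parts[2])
            volume = float(parts[3])
        except ValueError as exc:
            errors.append(f"{origin}:{lineno}: {exc}")
            continue
        peaks.append(CrossPeak(atom_a=atom_a, atom_b=atom_b, volume=volume))
    if errors:
        raise ValueError("peak list errors:\n" + "\n".join(errors))
    return peaks


def write_peaklist(peaks: Sequence[CrossPeak], path) -> None:
    with open(path, "w") as fh:
        fh.write("# assignment  w1_ppm  w2_ppm  volume\n")
        for p in peaks:
            a = f"{p.atom_a[0]}{p.atom_a[1]}-{p.atom_b[0]}{p.atom_b[1]}"
            fh.write(f"{a}  0.0  0.0  {p.volume:.8g}\n")


# ---------------------------------------------------------------------------
# fluorescence pattern CSV (block, wavelength_nm, intensity)


def write_pattern_csv(pattern: FluorescencePattern, path) -> None:
    wl_all, edges, names = synth._fluor_grid()
    if edges != pattern.block_edges:
        wl_all = np.arange(len(pattern.intensities), dtype=float)
    rows = []
    for i, name in enumerate(pattern.block_names):
        seg = slice(pattern.block_edges[i], pattern.block_edges[i + 1])
        for w, y in zip(wl_all[seg], pattern.intensities[seg]):
            rows.append((name, w, y))
    pd.DataFrame(rows, columns=["block", "wavelength_nm", "intensity"]).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_pattern_csv(path, sample: str | None = None) -> FluorescencePattern:
    df = pd.read_csv(path)
    blocks = list(dict.fromkeys(df["block"]))
    chunks = [df[df["block"] == b]["intensity"].to_numpy(dtype=float) for b in blocks]
    edges = np.cumsum([0] + [len(c) for c in chunks])
    return FluorescencePattern(
        sample=sample or str(path),
        intensities=np.concatenate(chunks),
        block_edges=tuple(int(e) for e in edges),
        block_names=tuple(blocks),
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Configuration of the synthetic end-to-end run (YAML-loadable)."""

    out_dir: str
    seed: int = 0
    c_uv: float = presets.COND_UV_SRESEG16.c
    c_nmr: float = presets.COND_NMR_SRESEG16.c
    c_ref: float = 1.0
    duplex_fraction_13C: float = 0.07  # generator target at 13 °C, c_nmr
    dH_duplex: float = -217e3
    fluor_K_du: float = presets.K_DU_FLUOR_PER_M
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("c_uv", "c_nmr", "c_ref"):
            if key in raw:
                raw[key] = parse_concentration(raw[key])
        return cls(**raw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Full synthetic workflow: generate → SVD → fits → joint fit → report.

    Writes decomposition CSVs, fit JSONs, the duplex-fraction curve,
    NOE distance and restraint tables, and a run log; returns the report
    dict.  Any stage error aborts with the stage name; partial outputs are
    left in place.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"meltfold pipeline, seed={cfg.seed}"]
    report: dict = {"seed": cfg.seed}
    scfg = synth.SynthConfig(seed=cfg.seed)

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - stage boundary
                (out / "run.log").write_text("\n".join(log_lines) + "\n")
                raise PipelineError(name, exc) from exc
            log_lines.append(f"stage {name}: ok")
            return result

        return deco

    cond_uv = EquilibriumConditions(c=cfg.c_uv, c_ref=cfg.c_ref)
    cond_nmr = EquilibriumConditions(c=cfg.c_nmr, c_ref=cfg.c_ref)
    hairpin = presets.SRESEG16_NMR_HAIRPIN

    @stage("synth")
    def _synth():
        dupl = synth.solve_duplex_entropy(
            cfg.duplex_fraction_13C, 13.0, cond_nmr, hairpin, cfg.dH_duplex
        )
        series = synth.synth_uv_series(
            scfg, thermo=hairpin, model="combined", cond=cond_uv, duplex=dupl
        )
        profiles = synth.synth_shift_profiles(
            scfg, thermo=hairpin, model="combined", cond=cond_nmr, duplex=dupl
        )
        write_spectral_series(series, out / "uv_series.csv")
        write_shift_profiles(profiles, out / "shift_profiles.csv")
        return dupl, series, profiles

    duplex_true, series, profiles = _synth

    @stage("svd")
    def _svd():
        dec = factors.decompose(read_spectral_series(out / "uv_series.csv"))
        M = factors.estimate_dimension(dec)
        pd.DataFrame(dec.S.T).to_csv(out / "svd_S.csv", index=False)
        pd.DataFrame(dec.V).to_csv(out / "svd_V.csv", index=False)
        pd.DataFrame({"W": dec.W}).to_csv(out / "svd_W.csv", index=False)
        (out / "svd_summary.json").write_text(
            json.dumps({"factor_dimension": M, "singular_values": dec.W[:8].tolist()},
                       indent=2)
        )
        return dec, M

    dec, M = _svd
    report["factor_dimension"] = M

    @stage("fit-uv")
    def _fit_uv():
        fit = meltfit.fit_uv_scores(dec, max(2, min(M, 4)), "hairpin", cond_uv)
        payload = {
            "model": fit.model,
            "Tm_celsius": fit.tm_celsius,
            "dH_J_mol": fit.params.dH,
            "dS_J_mol_K": fit.params.dS,
            "stderr": fit.stderr,
            "rss": fit.rss,
        }
        (out / "fit_uv.json").write_text(json.dumps(payload, indent=2))
        return fit

    fit_uv = _fit_uv
    report["uv_Tm_celsius"] = fit_uv.tm_celsius

    @stage("fit-nmr")
    def _fit_nmr():
        fit = meltfit.fit_shift_profiles(profiles, "hairpin", cond_nmr, shared=True)
        per = meltfit.per_resonance_tm(profiles, "hairpin", cond_nmr)
        (out / "fit_nmr.json").write_text(
            json.dumps(
                {
                    "Tm_celsius": fit.tm_celsius,
                    "dH_J_mol": fit.params.dH,
                    "dS_J_mol_K": fit.params.dS,
                    "stderr": fit.stderr,
                    "per_resonance": per,
                },
                indent=2,
                default=float,
            )
        )
        return fit

    fit_nmr = _fit_nmr
    report["nmr_Tm_celsius"] = fit_nmr.tm_celsius

    @stage("fit-joint")
    def _joint():
        res = meltfit.fit_joint((dec, max(2, min(M, 4)), cond_uv), (profiles, cond_nmr))
        grid = np.arange(5.0, 86.0, 1.0)
        curve = meltfit.duplex_fraction_curve(res, grid, cfg.c_nmr)
        pd.DataFrame(
            {"temperature_C": grid, "duplex_strand_fraction": curve}
        ).to_csv(out / "duplex_fraction_curve.csv", index=False)
        f_h, f_du, f_un = res.fraction_at(13.0, cfg.c_nmr)
        (out / "fit_joint.json").write_text(
            json.dumps(
                {
                    "hairpin": {"Tm_celsius": res.Tm_hairpin - 273.15,
                                "dH_J_mol": res.hairpin_params.dH},
                    "duplex": {"Tm_celsius": res.Tm_duplex - 273.15,
                               "dH_J_mol": res.duplex_params.dH},
                    "duplex_fraction_13C_percent": 100.0 * f_du,
                    "non_identifiable": res.non_identifiable,
                },
                indent=2,
            )
        )
        return res, f_du

    joint, f_du_13 = _joint
    report["duplex_fraction_13C_percent"] = 100.0 * f_du_13

    @stage("noe")
    def _noe():
        geometry = [
            (("C-4", "H5"), ("C-4", "H6"), 2.9),
            (("C-5", "H5"), ("C-5", "H6"), 2.9),
            (("A6", "H8"), ("A6", "H1'"), 3.7),
            (("T-2", "M7"), ("A-1", "H8"), 3.4),
            (("G5", "H8"), ("A6", "H1'"), 3.2),
        ]
        peaks = synth.synth_noesy_peaks(geometry, scale=1e6, cfg=scfg)
        write_peaklist(peaks, out / "noesy_peaks.list")
        dists = noe.peaks_to_distances(read_peaklist(out / "noesy_peaks.list"))
        (out / "restraints.tsv").write_text(noe.export_restraints(dists))
        return dists

    distances = _noe
    report["n_noe_distances"] = len(distances)

    @stage("fluor")
    def _fluor():
        K_h = assoc_constant(hairpin, celsius_to_kelvin(presets.FLUOR_TEMPERATURE_C))
        refs = synth.make_reference_patterns(scfg)
        titration = synth.synth_titration(scfg, cfg.fluor_K_du, K_h, refs)
        res = fluor.fit_association_constant(titration, refs, K_h)
        (out / "fluor_fit.json").write_text(
            json.dumps(
                {
                    "K_du_per_uM": res.K_du_per_uM,
                    "ci_per_uM": list(res.ci_per_uM),
                    "upper_bound_only": res.upper_bound_only,
                },
                indent=2,
            )
        )
        return res

    fl = _fluor
    report["fluor_K_du_per_uM"] = fl.K_du_per_uM

    log_lines.append(f"seeds: synth={cfg.seed} (streams uv=1 nmr=2 noe=3 fluor=4)")
    log_lines.append(f"report: {json.dumps(report)}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
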