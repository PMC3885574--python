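"""Plain-text I/O: thermogram TSVs, cohort manifests, peak lists.

Thermograms travel as two-column TSV files (temperature_C, signal), one
file per scan, tied together by a cohort manifest TSV.  MALDI spectra are
three-column TSV peak lists (mz, intensity, replicate) per sample, tied
together by a sample sheet TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ThermogramRecord
from .synthetic import Spectrum


def write_thermogram(record: ThermogramRecord, path) -> None:
    """Write one scan as a two-column TSV (temperature_C, signal)."""
    df = pd.DataFrame(
        {"temperature_C": record.temperatures, "signal": record.values}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_thermogram(
    path,
    sample_id: str | None = None,
    group: str | None = None,
    stage: str = "raw",
    protein_conc: float | None = None,
) -> ThermogramRecord:
    """Read a two-column thermogram TSV."""
    df = pd.read_csv(path, sep="\t")
    if not {"temperature_C", "signal"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns temperature_C, signal")
    return ThermogramRecord(
        sample_id=sample_id or Path(path).stem,
        group=group,
        temperatures=df["temperature_C"].to_numpy(float),
        values=df["signal"].to_numpy(float),
        stage=stage,
        protein_conc=protein_conc,
    )


def write_cohort(manifest: pd.DataFrame, records: dict, out_dir) -> Path:
    """Write a simulated cohort: one TSV per scan plus a manifest TSV.

    ``records`` maps sample_id to a (sample scan, buffer scan) pair, as
    produced by :func:`thermopept.synthetic.simulate_cohort`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for row in manifest.to_dict("records"):
        sample_id = row["sample_id"]
        sample, buffer = records[sample_id]
        sample_file = f"{sample_id}.tsv"
        buffer_file = f"{sample_id}_buffer.tsv"
        write_thermogram(sample, out_dir / sample_file)
        write_thermogram(buffer, out_dir / buffer_file)
        rows.append({**row, "sample_file": sample_file,
                     "buffer_file": buffer_file})
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_cohort(manifest_path) -> tuple[pd.DataFrame, dict]:
    """Read a cohort manifest and its raw scan pairs."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    records = {}
    for row in manifest.to_dict("records"):
        sample = read_thermogram(
            manifest_path.parent / row["sample_file"],
            sample_id=row["sample_id"],
            group=row.get("group"),
            protein_conc=row.get("protein_conc_g_per_L"),
        )
        buffer = read_thermogram(
            manifest_path.parent / row["buffer_file"],
            sample_id=f"{row['sample_id']}_buffer",
            group=row.get("group"),
        )
        records[row["sample_id"]] = (sample, buffer)
    return manifest, records


def write_peak_list(spectra: list[Spectrum], path) -> None:
    """Write all replicates of one sample-fraction as a 3-column TSV."""
    frames = [
        pd.DataFrame(
            {"mz": sp.mz, "intensity": sp.intensity, "replicate": sp.replicate}
        )
        for sp in spectra
    ]
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_peak_list(
    path, sample_id: str, group: str, fraction: str
) -> list[Spectrum]:
    """Read a 3-column peak-list TSV back into replicate spectra."""
    df = pd.read_csv(path, sep="\t")
    spectra = []
    for rep, sub in df.groupby("replicate"):
        sub = sub.sort_values("mz")
        spectra.append(
            Spectrum(
                sample_id=sample_id,
                group=group,
                fraction=fraction,
                replicate=int(rep),
                mz=sub["mz"].to_numpy(float),
                intensity=sub["intensity"].to_numpy(float),
            )
        )
    return spectra


def write_ms_cohort(spectra: list[Spectrum], out_dir) -> Path:
    """Write an MS cohort: peak-list TSVs plus a sample sheet TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_key: dict[tuple, list[Spectrum]] = {}
    for sp in spectra:
        by_key.setdefault((sp.sample_id, sp.group, sp.fraction), []).append(sp)
    rows = []
    for (sample_id, group, fraction), reps in by_key.items():
        fname = f"{sample_id}_{fraction}.tsv"
        write_peak_list(reps, out_dir / fname)
        rows.append(
            {
                "sample_id": sample_id,
                "group": group,
                "fraction": fraction,
                "file": fname,
            }
        )
    sheet_path = out_dir / "samples.tsv"
    pd.DataFrame(rows).to_csv(sheet_path, sep="\t", index=False)
    return sheet_path


def read_ms_cohort(sheet_path) -> list[Spectrum]:
    """Read a sample sheet TSV and its peak-list files."""
    sheet_path = Path(sheet_path)
    sheet = pd.read_csv(sheet_path, sep="\t")
    spectra: list[Spectrum] = []
    for row in sheet.to_dict("records"):
        spectra.extend(
            read_peak_list(
                sheet_path.parent / row["file"],
                sample_id=row["sample_id"],
                group=row["group"],
                fraction=row["fraction"],
            )
        )
    return spectra
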