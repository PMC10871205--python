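"""CSV readers and writers for the pipeline's tidy tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

STRIDE_COLUMNS = [
    "participant_id", "group", "phase", "stride",
    "fast_step_cm", "slow_step_cm", "feedback_on",
]


def write_cohort(strides: pd.DataFrame, truth: pd.DataFrame, outdir) -> None:
    """Write one stride CSV per participant plus a cohort manifest.

    The manifest carries the generating parameters and any covariate;
    latent columns (``ai_latent``, ``injected_outlier``) stay out of the
    per-participant files, mimicking what a real experiment records.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pid, grp in strides.groupby("participant_id", sort=False):
        cols = [c for c in STRIDE_COLUMNS if c in grp.columns]
        grp[cols].to_csv(outdir / f"{pid}.csv", index=False)
    truth.to_csv(outdir / "manifest.csv", index=False)


def read_cohort(indir) -> pd.DataFrame:
    """Read every per-participant stride CSV in a directory (skips the manifest)."""
    indir = Path(indir)
    frames = []
    for path in sorted(indir.glob("*.csv")):
        if path.name == "manifest.csv":
            continue
        frames.append(pd.read_csv(path))
    if not frames:
        raise FileNotFoundError(f"no participant CSVs found in {indir}")
    return pd.concat(frames, ignore_index=True)


def read_manifest(indir) -> pd.DataFrame:
    return pd.read_csv(Path(indir) / "manifest.csv")


def write_preprocessed(ai_df: pd.DataFrame, path) -> None:
    ai_df.to_csv(path, index=False)


def read_preprocessed(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fits(fits: dict, path) -> None:
    """Flatten {participant -> {model -> FitResult}} into a fits CSV."""
    rows = []
    for pid, per_model in fits.items():
        for model, f in per_model.items():
            row = {"participant_id": pid, "model": model,
                   "sse": f.sse, "r2": f.r2, "n_obs": f.n_obs}
            row.update(f.params_dict())
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fits(path) -> pd.DataFrame:
    return pd.read_csv(path)
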