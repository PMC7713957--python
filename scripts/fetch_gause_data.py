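#!/usr/bin/env python
"""Fetch the digitized historical microcosm datasets (network required).

Downloads the archived gauseR data collection (Zenodo DOI
10.5281/zenodo.4058426, mirrored on GitHub), converts the bundled R data
files to long-format CSV (``time,species,abundance,treatment``) via Rscript,
and writes them under ``data/gause/``.  The acceptance tests that compare
fitted parameters with the classically reported values read those CSVs.

The conversion uses column-name heuristics (a time-like column, an optional
treatment column, remaining numeric columns as species abundances); inspect
the written files if a dataset uses an unexpected layout.  Nothing is
downloaded or written unless explicitly run; the rest of the package and test
suite is fully self-contained.
"""

from __future__ import annotations

import argparse
import shutil
import subprocess
import sys
import tarfile
import tempfile
import urllib.request
import zipfile
from pathlib import Path

URLS = [
    "https://zenodo.org/api/records/4058426/files-archive",
    "https://github.com/adamtclark/gauseR/archive/refs/heads/master.tar.gz",
]

DEFAULT_DATASETS = ["gause_1934_science_f02_03", "gause_1934_science_f01",
                    "mclaren_1994_f03", "huffaker_1963"]

TIME_NAMES = ("day", "time", "date", "year", "week", "t")
META_NAMES = ("paper", "figure", "fig", "page", "table", "source")

R_DUMP = """
args <- commandArgs(trailingOnly = TRUE)
load(args[1])
name <- args[2]
write.csv(get(name), file = args[3], row.names = FALSE)
"""


def download(workdir: Path) -> Path:
    for url in URLS:
        dest = workdir / url.split("/")[-1].split("?")[0]
        try:
            print(f"downloading {url} ...")
            urllib.request.urlretrieve(url, dest)
            return dest
        except Exception as exc:  # noqa: BLE001 - report and try next mirror
            print(f"  failed: {exc}", file=sys.stderr)
    raise SystemExit("no mirror reachable; this script needs network access")


def extract(archive: Path, workdir: Path) -> Path:
    out = workdir / "extracted"
    out.mkdir(exist_ok=True)
    if zipfile.is_zipfile(archive):
        with zipfile.ZipFile(archive) as z:
            z.extractall(out)
        # the Zenodo files-archive may contain a nested source archive
        for inner in out.rglob("*.tar.gz"):
            with tarfile.open(inner) as t:
                t.extractall(out)
    else:
        with tarfile.open(archive) as t:
            t.extractall(out)
    return out


def rda_to_raw_csv(rda: Path, name: str, dest: Path) -> bool:
    script = dest.parent / "_dump.R"
    script.write_text(R_DUMP)
    proc = subprocess.run(
        ["Rscript", "--vanilla", str(script), str(rda), name, str(dest)],
        capture_output=True, text=True)
    if proc.returncode != 0:
        print(f"  Rscript failed for {name}: {proc.stderr.strip()}",
              file=sys.stderr)
        return False
    return True


def reshape_long(raw_csv: Path, out_csv: Path) -> None:
    import pandas as pd

    df = pd.read_csv(raw_csv)
    cols = {c.lower(): c for c in df.columns}
    time_col = next((cols[n] for n in TIME_NAMES if n in cols), None)
    if time_col is None:
        raise ValueError(f"no time-like column in {list(df.columns)}")
    treat_col = cols.get("treatment")
    value_cols = [c for c in df.columns
                  if c not in (time_col, treat_col)
                  and c.lower() not in META_NAMES
                  and pd.api.types.is_numeric_dtype(df[c])]
    if not value_cols:
        raise ValueError(f"no abundance columns in {list(df.columns)}")
    long = df.melt(id_vars=[c for c in (time_col, treat_col) if c],
                   value_vars=value_cols, var_name="species",
                   value_name="abundance")
    long = long.rename(columns={time_col: "time"})
    long["treatment"] = long[treat_col] if treat_col else ""
    long = long.dropna(subset=["abundance"])
    long[["time", "species", "abundance", "treatment"]].to_csv(
        out_csv, index=False)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datasets", nargs="*", default=DEFAULT_DATASETS)
    ap.add_argument("--out-dir", default="data/gause", type=Path)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    with tempfile.TemporaryDirectory() as tmp:
        workdir = Path(tmp)
        archive = download(workdir)
        tree = extract(archive, workdir)
        rda_files = {p.stem: p for p in tree.rglob("*.rda")}
        if shutil.which("Rscript") is None:
            raise SystemExit("Rscript not found; needed to convert .rda")
        for name in args.datasets:
            if name not in rda_files:
                print(f"  dataset {name} not found in archive", file=sys.stderr)
                continue
            raw = workdir / f"{name}_raw.csv"
            if not rda_to_raw_csv(rda_files[name], name, raw):
                continue
            out = args.out_dir / f"{name}.csv"
            reshape_long(raw, out)
            print(f"wrote {out}")


if __name__ == "__main__":
    main()
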