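#!/usr/bin/env python
"""Optional reproduction helper: fetch the GSE129534 expression matrix.

Downloads the series' supplementary processed-counts file from the GEO FTP
mirror and prepares ``data/GSE129534_counts.tsv`` plus a design template.
Requires network access; the analysis library itself never downloads
anything.

The NOR/FRA assignment of the 16 samples is taken from the series metadata
(frailty status per GSM). After running this script, review
``data/GSE129534_design.tsv`` against the sample characteristics printed to
stdout before using it: the two labels must be NOR (reference, non-frail)
and FRA (condition, frail), 8 samples each. With the data in place,
``tests/test_acceptance.py::test_criterion_7_accession_high_expression_count``
un-skips and ``scripts/acceptance.py`` reports target t1.
"""

from __future__ import annotations

import gzip
import io
import re
import sys
import urllib.request
from pathlib import Path

BASE = "https://ftp.ncbi.nlm.nih.gov/geo/series/GSE129nnn/GSE129534"
DATA_DIR = Path(__file__).resolve().parent.parent / "data"


def fetch(url: str) -> bytes:
    print(f"fetching {url}", file=sys.stderr)
    with urllib.request.urlopen(url, timeout=120) as resp:
        return resp.read()


def main() -> int:
    DATA_DIR.mkdir(exist_ok=True)

    # 1. series matrix: sample titles and characteristics (for the design)
    matrix_url = f"{BASE}/matrix/GSE129534_series_matrix.txt.gz"
    series = gzip.decompress(fetch(matrix_url)).decode("utf-8", "replace")
    gsm_ids, titles, frailty_lines = [], [], []
    for line in series.splitlines():
        if line.startswith("!Sample_geo_accession"):
            gsm_ids = [f.strip('"') for f in line.split("\t")[1:]]
        elif line.startswith("!Sample_title"):
            titles = [f.strip('"') for f in line.split("\t")[1:]]
        elif line.startswith("!Sample_characteristics") and "frail" in line.lower():
            frailty_lines = [f.strip('"') for f in line.split("\t")[1:]]
    print("sample metadata:", file=sys.stderr)
    design_rows = []
    for i, gsm in enumerate(gsm_ids):
        title = titles[i] if i < len(titles) else ""
        char = frailty_lines[i] if i < len(frailty_lines) else ""
        blob = f"{title} {char}".lower()
        if re.search(r"non[- ]?frail|\bnor\b|control", blob):
            group = "NOR"
        elif re.search(r"frail|\bfra\b", blob):
            group = "FRA"
        else:
            group = "REVIEW_ME"
        design_rows.append((gsm, group))
        print(f"  {gsm}\t{group}\t{title}\t{char}", file=sys.stderr)

    design_path = DATA_DIR / "GSE129534_design.tsv"
    with open(design_path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for gsm, group in design_rows:
            fh.write(f"{gsm}\t{group}\n")
    print(f"wrote {design_path} - REVIEW the group column before use",
          file=sys.stderr)

    # 2. supplementary processed counts; file name discovered from the listing
    listing = fetch(f"{BASE}/suppl/").decode("utf-8", "replace")
    candidates = sorted(set(re.findall(r"GSE129534[^\"'<>\s]*", listing)))
    counts_name = next(
        (c for c in candidates if c.lower().endswith((".txt.gz", ".tsv.gz",
                                                      ".csv.gz"))),
        None,
    )
    if counts_name is None:
        print(f"no counts-like supplementary file found among {candidates}; "
              "download manually and save as data/GSE129534_counts.tsv",
              file=sys.stderr)
        return 1
    raw = fetch(f"{BASE}/suppl/{counts_name}")
    text = gzip.decompress(raw).decode("utf-8", "replace")
    if "," in text.splitlines()[0] and "\t" not in text.splitlines()[0]:
        text = "\n".join(ln.replace(",", "\t") for ln in text.splitlines())
    counts_path = DATA_DIR / "GSE129534_counts.tsv"
    counts_path.write_text(text)
    print(f"wrote {counts_path}; verify its columns match the design sample "
          "identifiers (rename header columns to GSM accessions if needed)",
          file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
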