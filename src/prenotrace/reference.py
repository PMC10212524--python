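"""Published quantitative deuterium-incorporation summary for Arabidopsis
polyisoprenoids.

These are the reported per-condition isotopologue percentages and average
deuterated-unit counts for Pren-11 and Dol-16 after hydroponic feeding with
deuterated deoxyxylulose (D-DX) and mevalonolactone (D-MVL), singly or in
competition with the natural-abundance precursor of the other pathway. They
serve as worked-example inputs (e.g. turning a non-deuteriated percentage
into a deuteriation level) and as realism anchors for the synthetic study
design; they are not recomputable from raw data within this package.

Labeling keys: ``"D-DX"`` and ``"D-MVL"`` are single-precursor experiments;
``"D-DX/MVL"`` and ``"D-MVL/DX"`` are competitive (the deuterated precursor
is named first).
"""

from __future__ import annotations

#: (compound, tissue, labeling) -> reported metrics (percent / unit counts)
REPORTED_INCORPORATION: dict[tuple[str, str, str], dict[str, float]] = {
    ("Pren-11", "leaves", "D-DX"):     {"non_deuteriated": 76, "fully_deuteriated": 0, "average_units": 0.7},
    ("Pren-11", "leaves", "D-DX/MVL"): {"non_deuteriated": 68, "fully_deuteriated": 0, "average_units": 1.1},
    ("Pren-11", "leaves", "D-MVL"):    {"non_deuteriated": 98, "fully_deuteriated": 0, "average_units": 0.1},
    ("Pren-11", "leaves", "D-MVL/DX"): {"non_deuteriated": 73, "fully_deuteriated": 0, "average_units": 0.6},
    ("Dol-16", "leaves", "D-DX"):      {"non_deuteriated": 63, "fully_deuteriated": 0, "average_units": 1.5},
    ("Dol-16", "leaves", "D-DX/MVL"):  {"non_deuteriated": 50, "fully_deuteriated": 0, "average_units": 1.0},
    ("Dol-16", "leaves", "D-MVL"):     {"non_deuteriated": 19, "fully_deuteriated": 47, "average_units": 11.9},
    ("Dol-16", "leaves", "D-MVL/DX"):  {"non_deuteriated": 8, "fully_deuteriated": 7, "average_units": 8.7},
    ("Dol-16", "roots", "D-DX"):       {"non_deuteriated": 21, "fully_deuteriated": 19, "average_units": 7.9},
    ("Dol-16", "roots", "D-DX/MVL"):   {"non_deuteriated": 13, "fully_deuteriated": 0, "average_units": 5.8},
    ("Dol-16", "roots", "D-MVL"):      {"non_deuteriated": 5, "fully_deuteriated": 29, "average_units": 11.8},
    ("Dol-16", "roots", "D-MVL/DX"):   {"non_deuteriated": 29, "fully_deuteriated": 4, "average_units": 7.1},
}

#: reported unlabeled-molecule fraction of each deuterated substrate
REPORTED_SUBSTRATE_IMPURITY: dict[str, float] = {"DX": 0.029, "MVL": 0.007}

#: reported natural 13C abundance fitted globally from native envelopes
REPORTED_P13C: float = 0.0102
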