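"""Published summary tables from a seven-patient serial abdominal CT study.

A retrospective cohort of seven adult patients received 5–20 abdominal CT
scans each (92 scans total, 5 mm nominal sections); both adrenal glands
were hand-outlined on every scan and used as volumetrically stable
surrogate lesions.  The per-patient summary values shipped here — mean left
(LA) and right (RA) adrenal volumes, the per-patient volume COVs, and the
LA-vs-RA squared correlations — are the study-level reference data this
package's statistics are checked against.  Patient 7 had a left
adrenalectomy, so only the right gland is recorded (13 glands in total).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("volprec.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_mean_volume_table() -> pd.DataFrame:
    """Per-patient mean adrenal volumes (cm³); NaN where the gland is absent."""
    return _load("table2_mean_volumes.csv")


def load_cov_table() -> pd.DataFrame:
    """Per-patient volume-measurement COVs, in percent."""
    return _load("table3_covs.csv")


def load_r2_table() -> pd.DataFrame:
    """Per-patient squared correlation between paired LA/RA series."""
    return _load("table4_r2.csv")


def gland_precision_points() -> list[tuple[float, float]]:
    """(mean volume cm³, COV fraction) for each of the 13 evaluated glands.

    Joins the mean-volume and COV tables per gland; the input for the
    COV-vs-volume trend fit.
    """
    vols = load_mean_volume_table().set_index("patient_id")
    covs = load_cov_table().set_index("patient_id")
    points: list[tuple[float, float]] = []
    for side in ("left_adrenal", "right_adrenal"):
        joined = pd.concat(
            [vols[f"{side}_cm3"], covs[f"{side}_cov_pct"] / 100.0], axis=1
        ).dropna()
        points.extend(
            (float(v), float(c)) for v, c in joined.itertuples(index=False)
        )
    return points
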