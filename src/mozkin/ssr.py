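"""Single-sensillum-recording spike-rate statistic and dose–response tables.

The spike-rate statistic for one presentation is the number of spikes in
the 0.5 s stimulation window minus the number of spontaneous spikes in the
preceding 0.5 s, multiplied by two — i.e. a baseline-corrected rate in
spikes/s.  Negative rates are valid and indicate inhibition.  Windows are
half-open: the spontaneous window is [-0.5, 0) and the stimulation window
[0, 0.5), so a spike exactly at stimulus onset counts as evoked.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_config import SpikeRecord

logger = logging.getLogger(__name__)

DOSE_RESPONSE_COLUMNS = ["sensillum_id", "neuron", "genotype", "compound",
                         "log10_dose", "rate_spikes_s"]


def spike_rate(rec: SpikeRecord) -> float:
    """Baseline-corrected spike rate (spikes/s) of one presentation."""
    t = rec.spike_times_s
    stim = np.count_nonzero((t >= 0.0) & (t < rec.stim_duration_s))
    spont = np.count_nonzero((t >= -rec.stim_duration_s) & (t < 0.0))
    return float((stim - spont) * 2)


def dose_response(records: list[SpikeRecord]) -> pd.DataFrame:
    """One dose–response point per presentation.

    Duplicate (sensillum, neuron, compound, dose) presentations are kept as
    repeated measures and flagged with a warning; the mixed model downstream
    absorbs them through the sensillum-level random intercept.
    """
    rows = [(r.sensillum_id, r.neuron, r.genotype, r.compound,
             r.log10_dose, spike_rate(r)) for r in records]
    df = pd.DataFrame(rows, columns=DOSE_RESPONSE_COLUMNS)
    key = ["sensillum_id", "neuron", "compound", "log10_dose"]
    if len(df) and df.duplicated(key).any():
        n_dup = int(df.duplicated(key).sum())
        logger.warning("%d repeated presentations of the same (sensillum, neuron, "
                       "compound, dose); retained as repeated measures", n_dup)
    return df


def dose_response_summary(points: pd.DataFrame) -> pd.DataFrame:
    """Mean rate and standard error per genotype x compound x dose."""
    g = points.groupby(["genotype", "compound", "log10_dose"])["rate_spikes_s"]
    out = g.agg(mean_rate="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")
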