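"""Normalization of gene-family abundance profiles.

Two schemes are provided:

* **Relative normalization** — divide each sample by its total abundance, so
  values are per-sample fractions.  Depth-independent, but confounded by the
  average genome size of the community: a sample dominated by large genomes
  dilutes every gene's relative abundance, which can mask (or fabricate)
  between-sample variation.

* **Single-copy marker normalization** — divide each sample by a robust
  center of the abundances of universal single-copy marker families.  Because
  every genome carries exactly one copy of each marker, the marker signal
  measures "reads per genome", and the normalized values read as the average
  copy number of each gene family per genome in the community.  This is the
  yardstick idea of MUSiCC-style normalization; the learned intra-sample
  correction of the original MUSiCC tool is intentionally out of scope.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats as sps

from .profiles_io import FuncvarError, GeneProfile, MarkerSet

logger = logging.getLogger("funcvar")


def relative_normalize(profile: GeneProfile) -> GeneProfile:
    """Scale each sample to sum to 1.

    Raises on all-zero samples: a sample with no signal cannot be normalized
    and silently keeping it would poison downstream distances.
    """
    vals = profile.values
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        bad = [s for s, t in zip(profile.sample_ids, totals) if t <= 0]
        raise FuncvarError(f"cannot relative-normalize all-zero sample(s): {bad[:10]}")
    return profile.with_values(vals / totals[:, None], "relative")


def single_copy_normalize(profile: GeneProfile, markers: MarkerSet,
                          center: str = "median",
                          trim: float = 0.1) -> GeneProfile:
    """Calibrate abundances against universal single-copy marker families.

    Each sample is divided by the per-sample robust center (median by default,
    or a trimmed mean with ``center="trimmed_mean"``) of the abundances of the
    marker genes found in the profile.  Markers absent from the profile are
    treated as annotation gaps and contribute nothing to the center (they are
    *not* counted as zeros, which would bias the yardstick downward).

    After normalization the median marker value in every sample is exactly 1
    (under the median center) and all values read as average per-genome copy
    numbers.  The transform is invariant to global rescaling of the input
    (sequencing-depth independence).
    """
    present, missing = markers.intersect_profile(profile)
    if not present:
        raise FuncvarError("no marker genes present in profile")
    if len(present) < 0.5 * len(markers):
        warnings.warn(
            f"only {len(present)}/{len(markers)} marker genes found in profile; "
            "the single-copy yardstick may be unreliable", stacklevel=2)
    if missing:
        logger.info("single_copy_normalize: %d markers absent from profile",
                    len(missing))
    marker_vals = profile.data[present].to_numpy(dtype=float)
    if center == "median":
        centers = np.median(marker_vals, axis=1)
    elif center == "trimmed_mean":
        centers = sps.trim_mean(marker_vals, proportiontocut=trim, axis=1)
    else:
        raise FuncvarError(f"unknown center {center!r}")
    if (centers <= 0).any():
        bad = [s for s, c in zip(profile.sample_ids, centers) if c <= 0]
        raise FuncvarError(
            f"zero single-copy marker signal in sample(s): {bad[:10]}")
    return profile.with_values(profile.values / centers[:, None], "copy_number")
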