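"""End-to-end scoring of one trial: filter -> features -> fuzzy scores."""

from __future__ import annotations

from .config import ScoringConfig, default_config
from .features import FeatureVector, extract_features
from .scoring import make_test_definition, score_continuous, score_three_point
from .skeleton import SkeletonSequence, lowpass_filter


def score_trial(seq: SkeletonSequence, test_id: str,
                config: ScoringConfig | None = None,
                prefiltered: bool = False) -> dict:
    """Score one skeleton trial; returns a JSON-able report.

    The sequence is low-pass filtered (unless ``prefiltered``), the test's
    feature vector extracted, and both the continuous score ``fm_ca`` and
    the crisp three-point score ``fm3a`` computed under ``config``.
    """
    config = config or default_config()
    if not prefiltered:
        seq = lowpass_filter(seq, cutoff=config.filter_cutoff_hz,
                             order=config.filter_order)
    fv = extract_features(seq, test_id,
                          desired_posture=config.desired_posture,
                          rest_fraction=config.rest_fraction,
                          threshold_fraction=config.threshold_fraction)
    testdef = make_test_definition(test_id, config)
    return {
        "test_id": test_id,
        "side": seq.side,
        "n_frames": len(seq),
        "features_deg": {k: round(float(v), 6) for k, v in fv.values.items()},
        "fm_ca": round(score_continuous(fv, testdef), 6),
        "fm3a": score_three_point(fv, testdef, tau=config.tau),
    }
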