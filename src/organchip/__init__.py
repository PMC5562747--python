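"""organchip: beat kinetics, viability and PK/PD simulation for organ-on-a-chip data."""

__version__ = "0.1.0"

from .beats import (BeatMetrics, BeatParams, BeatSeries, analyze_trace, beat_rate,
                    detect_beats, detect_cessation, windowed_rates)
from .errors import (ArgumentError, CapacityError, FormatError, InputError,
                     OrganChipError)
from .io_media import (FrameSequence, TwoChannelImage, read_frames, read_two_channel,
                       to_grayscale, write_frames, write_report, write_two_channel)
from .motion import (MotionParams, MotionTrace, auto_threshold, compute_motion_trace,
                     frame_difference, threshold_motion)
from .pharm import (DoseResponse, HillFit, blockade_analysis, classify_timecourse,
                    fit_dose_response, fraction_recovered, percent_change)
from .pkpd import (CytokineConfig, ExperimentProtocol, PDParams, PKParams,
                   beat_rate_response, calibrate_pd_defaults, default_pd_params,
                   default_pk_params, simulate_clearance, simulate_cytokine_challenge,
                   simulate_three_tissue_scenario, simulate_two_tissue_experiment)
from .synth import (ImageTruth, VideoTruth, generate_beating_video,
                    generate_experiment_dataset, generate_livedead_image)
from .viability import (ViabilityParams, ViabilityResult, count_live_dead,
                        segment_channel)


def analyze_video(seq, motion_params=None, beat_params=None):
    """Convenience: motion trace + beat detection + metrics for one clip.

    Returns ``(trace, series, metrics)``.
    """
    from .beats import analyze_trace as _analyze
    from .motion import compute_motion_trace as _trace

    trace = _trace(seq, motion_params)
    series, metrics = _analyze(trace, beat_params)
    return trace, series, metrics
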