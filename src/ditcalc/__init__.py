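"""ditcalc: absolute diet-induced thermogenesis from mouse calorimetry.

Workflow: read (or simulate) paired fasted/fed calorimetry traces, bin to
the 12-min analysis grid, fit the fasting EE ~ sqrt(activity) regression,
subtract the activity-matched prediction from fed EE, and integrate the
excess to a DIT total with intake- and EE-relative percentages.
"""

from .io import (
    CalorimetryError,
    CalorimetrySample,
    CalorimetryTrace,
    FeedingProtocol,
    TraceFormatError,
    TraceStructureError,
    TraceValidationError,
    read_dit_report,
    read_protocol,
    read_trace,
    write_dit_report,
    write_protocol,
    write_trace,
)
from .preprocess import (
    BinnedPoint,
    BinnedTrace,
    annotate_photoperiod,
    bin_trace,
    compute_ee,
    compute_rer,
    window_trace,
)
from .fasting_model import (
    FastingModel,
    ResidualDiagnostics,
    fit_fasting_model,
    predict_ee,
    residual_diagnostics,
    select_transform,
    transform_activity,
)
from .dit import (
    DITResult,
    DITSeries,
    HourlySeries,
    aggregate_hourly,
    compute_dit_series,
    intake_per_bw,
    species_dit_ratio,
    summarize,
    total_auc,
)
from .group_stats import (
    ComparisonReport,
    GroupData,
    PairwiseRecord,
    compare_groups,
    games_howell,
    levene_test,
    tukey_hsd,
)
from .simulate import (
    SimConfig,
    SimGroundTruth,
    dit_kernel,
    dit_kernel_cumulative,
    generate_activity,
    generate_ee,
    invert_gas_exchange,
    simulate_cohort,
    simulate_mouse,
)

__version__ = "0.1.0"


def analyze_pair(fasted, fed, protocol, transform="sqrt"):
    """End-to-end analysis of one animal: traces in, :class:`DITResult` out.

    ``transform`` may be ``"auto"`` to pick the best-fitting activity
    transform by R² on the fasting data.
    """
    fasted_binned = bin_trace(fasted)
    fed_binned = bin_trace(fed)
    if transform == "auto":
        transform, _ = select_transform(fasted_binned)
    model = fit_fasting_model(fasted_binned, transform)
    series = compute_dit_series(fed_binned, model)
    return summarize(series, protocol)
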