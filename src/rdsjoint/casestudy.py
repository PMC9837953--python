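"""Published summary counts from the pooled asthma exacerbation case study.

Two placebo-controlled mepolizumab trials (52-week and 32-week nominal
follow-up) provide the motivating application for the joint model.  The
individual-level data are not public; only the printed summary counts below
are encoded, both to parameterize realistic synthetic scenarios and for
simple arithmetic consistency checks (pooled sample size after exclusions,
severe-exacerbation share, severe annual rate).
"""

from __future__ import annotations

# enrolment and exclusions
ENROLLED_TRIAL_52WK = 621
ENROLLED_TRIAL_32WK = 580
EXCLUDED_MISSING_COVARIATES = 84
EXCLUDED_OUTLYING_COVARIATES = 7

# pooled outcomes of the final analysis sample
N_EXACERBATIONS = 1128
N_SEVERE = 181
MEAN_FOLLOW_UP_YEARS = 0.78
ZERO_EVENT_PERCENT = 52.8
MEAN_DURATION_DAYS = 14.4


def pooled_sample_size() -> int:
    """Patients in the final pooled analysis sample after exclusions."""
    return (ENROLLED_TRIAL_52WK + ENROLLED_TRIAL_32WK
            - EXCLUDED_MISSING_COVARIATES - EXCLUDED_OUTLYING_COVARIATES)


def severe_share_percent() -> float:
    """Percentage of exacerbations classified severe (ED visit/admission)."""
    return 100.0 * N_SEVERE / N_EXACERBATIONS


def severe_annual_rate() -> float:
    """Severe exacerbations per patient-year in the pooled sample."""
    return N_SEVERE / (pooled_sample_size() * MEAN_FOLLOW_UP_YEARS)
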