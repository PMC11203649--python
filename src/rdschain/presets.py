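"""Published city-level parameterizations used as simulator defaults.

The 2021 two-city survey of Venezuelan migrant women (Manaus: 761
participants, 6 seeds; Boa Vista: 1268 participants, 9 seeds) printed,
per city, the marginal category distributions of the study variables, the
recruiter->recruit transition rows used for homophily diagnostics, and the
multivariate odds ratios for health-service use. Those printed values are
reproduced here (as proportions, not percentages) so synthetic datasets can
be generated with the survey's statistical structure as ground truth.
"""

from __future__ import annotations

import numpy as np

#: Marginal category distributions per city (printed point estimates,
#: renormalized below — printed columns carry rounding and can sum to 0.999).
_RAW_MARGINALS: dict[str, dict[str, dict[str, float]]] = {
    "Manaus": {
        "age_group": {"15-24": 0.367, "25-34": 0.351, "35-49": 0.281},
        "education": {"elementary": 0.122, "high_school": 0.665, "college": 0.212},
        "pregnant": {True: 0.056, False: 0.944},
        "self_rated_health": {"good": 0.664, "fair": 0.311, "poor": 0.025},
        "migratory_status": {
            "asylum_seeker": 0.294, "resident": 0.447, "irregular": 0.260,
        },
        "used_health_service_15d": {False: 0.689, True: 0.311},
        "chronic_disease": {True: 0.189, False: 0.811},
    },
    "BoaVista": {
        "age_group": {"15-24": 0.382, "25-34": 0.364, "35-49": 0.254},
        "education": {"elementary": 0.179, "high_school": 0.718, "college": 0.103},
        "pregnant": {True: 0.064, False: 0.936},
        "self_rated_health": {"good": 0.749, "fair": 0.236, "poor": 0.015},
        "migratory_status": {
            "asylum_seeker": 0.521, "resident": 0.429, "irregular": 0.051,
        },
        "used_health_service_15d": {False: 0.680, True: 0.320},
        "chronic_disease": {True: 0.165, False: 0.835},
    },
}

MARGINALS: dict[str, dict[str, dict[str, float]]] = {
    city: {
        var: {k: v / sum(d.values()) for k, v in d.items()}
        for var, d in by_var.items()
    }
    for city, by_var in _RAW_MARGINALS.items()
}

#: Recruiter->recruit transition rows per city and variable. Row key =
#: recruiter category; row value = distribution of the recruit's category.
TRANSITIONS: dict[str, dict[str, dict[str, dict[str, float]]]] = {
    "Manaus": {
        "age_group": {
            "15-24": {"15-24": 0.346, "25-34": 0.330, "35-49": 0.323},
            "25-34": {"15-24": 0.352, "25-34": 0.391, "35-49": 0.257},
            "35-49": {"15-24": 0.402, "25-34": 0.320, "35-49": 0.279},
        },
        "education": {
            "elementary": {"elementary": 0.174, "high_school": 0.591, "college": 0.235},
            "high_school": {"elementary": 0.126, "high_school": 0.657, "college": 0.216},
            "college": {"elementary": 0.096, "high_school": 0.708, "college": 0.196},
        },
        "migratory_status": {
            "asylum_seeker": {"asylum_seeker": 0.318, "resident": 0.439, "irregular": 0.243},
            "resident": {"asylum_seeker": 0.286, "resident": 0.462, "irregular": 0.251},
            "irregular": {"asylum_seeker": 0.275, "resident": 0.417, "irregular": 0.308},
        },
        "used_health_service_15d": {
            False: {False: 0.703, True: 0.297},
            True: {False: 0.665, True: 0.335},
        },
    },
    "BoaVista": {
        "age_group": {
            "15-24": {"15-24": 0.380, "25-34": 0.351, "35-49": 0.269},
            "25-34": {"15-24": 0.410, "25-34": 0.364, "35-49": 0.226},
            "35-49": {"15-24": 0.352, "25-34": 0.379, "35-49": 0.269},
        },
        "education": {
            "elementary": {"elementary": 0.192, "high_school": 0.736, "college": 0.072},
            "high_school": {"elementary": 0.185, "high_school": 0.708, "college": 0.108},
            "college": {"elementary": 0.126, "high_school": 0.759, "college": 0.115},
        },
        "migratory_status": {
            "asylum_seeker": {"asylum_seeker": 0.558, "resident": 0.405, "irregular": 0.037},
            "resident": {"asylum_seeker": 0.484, "resident": 0.457, "irregular": 0.059},
            "irregular": {"asylum_seeker": 0.433, "resident": 0.377, "irregular": 0.190},
        },
        "used_health_service_15d": {
            False: {False: 0.676, True: 0.324},
            True: {False: 0.687, True: 0.313},
        },
    },
}

#: Printed marginal ("Total") rows accompanying each transition block.
TRANSITION_TOTALS: dict[str, dict[str, dict[str, float]]] = {
    "Manaus": {
        "age_group": {"15-24": 0.367, "25-34": 0.351, "35-49": 0.281},
        "education": {"elementary": 0.122, "high_school": 0.665, "college": 0.212},
        "migratory_status": {"asylum_seeker": 0.294, "resident": 0.447, "irregular": 0.260},
        "used_health_service_15d": {False: 0.689, True: 0.311},
    },
    "BoaVista": {
        "age_group": {"15-24": 0.382, "25-34": 0.364, "35-49": 0.254},
        "education": {"elementary": 0.179, "high_school": 0.718, "college": 0.103},
        "migratory_status": {"asylum_seeker": 0.521, "resident": 0.429, "irregular": 0.051},
        "used_health_service_15d": {False: 0.680, True: 0.320},
    },
}

#: Reason-for-use distribution among service users (renormalized to sum 1;
#: the published percentages leave a small unlisted remainder).
REASON_DISTRIBUTION: dict[str, dict[str, float]] = {}
_raw_reasons = {
    "Manaus": {
        "illness_or_treatment": 20.1, "prenatal": 12.9, "vaccination": 19.5,
        "prevention_checkup_childcare": 22.5, "diagnostic_exams": 8.0, "dental": 2.4,
    },
    "BoaVista": {
        "illness_or_treatment": 25.1, "prenatal": 13.2, "vaccination": 15.2,
        "prevention_checkup_childcare": 17.6, "diagnostic_exams": 7.6, "dental": 4.4,
    },
}
for _city, _d in _raw_reasons.items():
    _tot = sum(_d.values())
    REASON_DISTRIBUTION[_city] = {k: v / _tot for k, v in _d.items()}

#: Multivariate odds ratios for health-service use (dichotomized covariates).
OUTCOME_ODDS_RATIOS: dict[str, dict[str, float]] = {
    "Manaus": {
        "age_15_24": 0.85, "college": 1.72, "pregnant": 5.57,
        "fair_poor_health": 1.52, "irregular": 0.76,
    },
    "BoaVista": {
        "age_15_24": 0.90, "college": 1.20, "pregnant": 2.04,
        "fair_poor_health": 1.62, "irregular": 0.80,
    },
}

#: Survey scale per city: seeds, non-seed recruits, and the coupon
#: acceptance probability that reproduces the observed recruits-per-recruiter
#: (about 2.6 in Manaus, about 2 in Boa Vista, out of 3 coupons).
CITY_DESIGN: dict[str, dict[str, float]] = {
    "Manaus": {"n_seeds": 6, "target_sample_size": 755,
               "coupon_acceptance_prob": 0.87},
    "BoaVista": {"n_seeds": 9, "target_sample_size": 1259,
                 "coupon_acceptance_prob": 0.67},
}


def transition_matrix_array(city: str, variable: str) -> tuple[list, np.ndarray]:
    """Categories and row-stochastic matrix for one printed transition block."""
    block = TRANSITIONS[city][variable]
    cats = list(block)
    mat = np.array([[block[r][c] for c in cats] for r in cats], dtype=float)
    mat = mat / mat.sum(axis=1, keepdims=True)
    return cats, mat
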