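"""Sample grouping into metastasis / non-metastasis / excluded.

Two policies are compared throughout the pipeline:

``tnm_only``
    The conventional definition: N0M0 patients form the non-metastasis
    group; anyone with nodal (N+) and/or distant (M+) metastasis forms the
    metastasis group. Recurrence is ignored.

``tnm_plus_recurrence``
    Recurrence-aware reclassification, motivated by the high false-negative
    rate of routine staging (micrometastases): an N0M0 patient who recurred
    after curative resection is treated as metastatic; an N+M0 patient who
    did not recur is dropped as a possible staging false positive; and,
    when adjuvant-treatment annotations exist, a non-recurrent N0M0 patient
    who received adjuvant therapy is dropped because their non-recurrence
    is uninformative (therapy may have suppressed an occult metastasis).
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .datatypes import (
    Group,
    GroupAssignment,
    MStage,
    NStage,
    Policy,
    SampleRecord,
    YesNoUnknown,
)

__all__ = [
    "group_tnm_only",
    "group_with_recurrence",
    "group_samples",
    "met_nonmet_ids",
    "assignments_to_frame",
]


def _check_unique(samples: Sequence[SampleRecord]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate sample_id in cohort: {dup!r}")


def group_tnm_only(samples: Sequence[SampleRecord]) -> list[GroupAssignment]:
    """Assign groups by TNM stage alone (recurrence ignored)."""
    _check_unique(samples)
    out: list[GroupAssignment] = []
    for s in samples:
        if s.n_stage is NStage.UNKNOWN or s.m_stage is MStage.UNKNOWN:
            out.append(
                GroupAssignment(
                    s.sample_id, Group.EXCLUDED, Policy.TNM_ONLY, "unknown_stage"
                )
            )
        elif s.n_stage is NStage.N_PLUS or s.m_stage is MStage.M_PLUS:
            out.append(
                GroupAssignment(
                    s.sample_id, Group.METASTASIS, Policy.TNM_ONLY, "N+_or_M+"
                )
            )
        else:
            out.append(
                GroupAssignment(
                    s.sample_id, Group.NON_METASTASIS, Policy.TNM_ONLY, "N0M0"
                )
            )
    return out


def group_with_recurrence(
    samples: Sequence[SampleRecord], adjuvant_available: bool = False
) -> list[GroupAssignment]:
    """Assign groups by TNM stage plus post-surgery recurrence.

    Rules, in order of precedence:

    1. M+ -> metastasis (distant metastasis trumps everything).
    2. Recurrence unknown -> excluded ("unknown_recurrence").
    3. M0 with recurrence -> metastasis (the occult-metastasis relabel).
    4. N+M0 without recurrence -> excluded ("N+M0_no_recurrence"),
       a potential staging false positive.
    5. N0M0 without recurrence -> non-metastasis, unless
       ``adjuvant_available`` and the patient received adjuvant therapy
       (excluded, "adjuvant_nonrecurrent"; unknown adjuvant status is
       likewise excluded, "unknown_adjuvant").

    Samples whose stage is too incomplete to place are excluded with
    reason "unknown_stage".
    """
    _check_unique(samples)
    pol = Policy.TNM_PLUS_RECURRENCE
    out: list[GroupAssignment] = []
    for s in samples:
        if s.m_stage is MStage.M_PLUS:
            out.append(GroupAssignment(s.sample_id, Group.METASTASIS, pol, "M+"))
        elif s.recurrence is YesNoUnknown.UNKNOWN:
            out.append(
                GroupAssignment(s.sample_id, Group.EXCLUDED, pol, "unknown_recurrence")
            )
        elif s.m_stage is MStage.UNKNOWN:
            out.append(
                GroupAssignment(s.sample_id, Group.EXCLUDED, pol, "unknown_stage")
            )
        elif s.recurrence is YesNoUnknown.YES:
            out.append(
                GroupAssignment(s.sample_id, Group.METASTASIS, pol, "M0_recurrence")
            )
        elif s.n_stage is NStage.UNKNOWN:
            out.append(
                GroupAssignment(s.sample_id, Group.EXCLUDED, pol, "unknown_stage")
            )
        elif s.n_stage is NStage.N_PLUS:
            out.append(
                GroupAssignment(
                    s.sample_id, Group.EXCLUDED, pol, "N+M0_no_recurrence"
                )
            )
        else:  # N0M0, no recurrence
            if adjuvant_available and s.adjuvant is YesNoUnknown.YES:
                out.append(
                    GroupAssignment(
                        s.sample_id, Group.EXCLUDED, pol, "adjuvant_nonrecurrent"
                    )
                )
            elif adjuvant_available and s.adjuvant is YesNoUnknown.UNKNOWN:
                out.append(
                    GroupAssignment(
                        s.sample_id, Group.EXCLUDED, pol, "unknown_adjuvant"
                    )
                )
            else:
                out.append(
                    GroupAssignment(
                        s.sample_id,
                        Group.NON_METASTASIS,
                        pol,
                        "N0M0_no_recurrence",
                    )
                )
    return out


def group_samples(
    samples: Sequence[SampleRecord],
    policy: Policy | str,
    adjuvant_available: bool = False,
) -> list[GroupAssignment]:
    policy = Policy(policy)
    if policy is Policy.TNM_ONLY:
        return group_tnm_only(samples)
    return group_with_recurrence(samples, adjuvant_available=adjuvant_available)


def met_nonmet_ids(
    assignments: Sequence[GroupAssignment],
) -> tuple[list[str], list[str]]:
    """Split assignments into (metastasis ids, non-metastasis ids)."""
    met = [a.sample_id for a in assignments if a.group is Group.METASTASIS]
    non = [a.sample_id for a in assignments if a.group is Group.NON_METASTASIS]
    return met, non


def assignments_to_frame(assignments: Sequence[GroupAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.sample_id, a.group.value, a.policy.value, a.reason)
            for a in assignments
        ],
        columns=["sample_id", "group", "policy", "reason"],
    )
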