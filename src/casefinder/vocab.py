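"""Default coded vocabularies and code sets.

Everything here is configuration, not constant: the psychosis definition
covers schizophrenia, schizoaffective disorder and other psychotic disorders
while deliberately excluding bipolar disorder (F30-F31), psychotic depression
(F32.3/F33.3) and dementia (F00-F03, G30), which can involve psychotic
symptoms but are out of scope for the case definition.  Users can substitute
their own :class:`~casefinder.model.CodeSet` objects anywhere these defaults
are accepted.
"""

from __future__ import annotations

from .model import CodeSet, Vocabularies

#: ICD-10 chapters counted as psychosis (prefix match: F20 covers F20.0 ...).
PSYCHOSIS_ICD10 = CodeSet(
    "psychosis",
    frozenset({"F20", "F21", "F22", "F23", "F24", "F25", "F28", "F29"}),
    match_mode="prefix",
)

#: Dementia codes used by the 55-65 older-age exclusion.
DEMENTIA_ICD10 = CodeSet(
    "dementia", frozenset({"F00", "F01", "F02", "F03", "G30"}), match_mode="prefix"
)

#: Psychotic depression codes used by the 55-65 older-age exclusion.
PSYCHOTIC_DEPRESSION_ICD10 = CodeSet(
    "psychotic_depression", frozenset({"F32.3", "F33.3"}), match_mode="exact"
)

#: Mental-health clusters whose likely primary diagnosis includes psychosis
#: (the clustering tool's psychosis super-class).
PSYCHOSIS_CLUSTERS = CodeSet(
    "psychosis_clusters", frozenset(range(10, 18)), match_mode="exact"
)

#: Reason-for-referral vocabulary, zero-padded two-character strings.
#: 01 = (suspected) first-episode psychosis, 02 = ongoing or recurrent
#: psychosis, 18 = in crisis.
REFERRAL_REASONS = frozenset(f"{i:02d}" for i in range(1, 29))

#: HoNOS instrument versions and the item number of "problems associated
#: with hallucinations and delusions" in each (item 6, 7 or 8 by version).
HONOS_ITEM_MAP = {
    "working-age": 6,
    "65+": 6,
    "ABI": 6,
    "CA-CR": 7,
    "LD": 8,
}

#: Highest item number per HoNOS version (for schema validation).
HONOS_MAX_ITEM = {
    "working-age": 12,
    "65+": 12,
    "ABI": 12,
    "CA-CR": 15,
    "LD": 18,
}

#: Qualifying threshold on the hallucinations/delusions item.
HONOS_THRESHOLD = 3

DEFAULT_VOCAB = Vocabularies(
    referral_reasons=REFERRAL_REASONS,
    cluster_codes=frozenset(range(0, 22)),
    honos_versions=frozenset(HONOS_ITEM_MAP),
    honos_max_item=HONOS_MAX_ITEM,
)
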