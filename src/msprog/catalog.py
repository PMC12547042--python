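"""Disease-modifying-treatment catalogue and default code lists.

DMTs are categorised along two axes used throughout MS pharmacoepidemiology:
route class (monoclonal antibody / oral / injectable) and efficacy tier
(platform / high-efficacy, following the European and Italian regulatory
classification).  Code lists (MS diagnosis code, severe-disability codes,
MS-related outpatient service categories) ship with documented defaults and
are user-configurable — regional extracts differ in their coding habits.
"""

from __future__ import annotations

from dataclasses import dataclass, field


MAB = "MAB"
ORAL = "oral"
INJECTABLE = "injectable"
PLATFORM = "platform"
HIGH_EFFICACY = "high_efficacy"

#: ICD-9-CM diagnosis code for multiple sclerosis.
MS_ICD9_CODE = "340"

#: Outpatient service categories recognised by the feature builder.
OUTPATIENT_CATEGORIES = (
    "consultation",
    "diagnostic",
    "laboratory",
    "procedure",
    "therapeutic",
    "rehabilitation",
)


@dataclass(frozen=True)
class DMTEntry:
    route_class: str  # MAB | oral | injectable
    efficacy_tier: str  # platform | high_efficacy


#: Default drug_name -> (route class, efficacy tier) map.
#: Monoclonal antibodies are all high-efficacy; orals split between the
#: platform tier (dimethyl fumarate, teriflunomide) and high-efficacy
#: (cladribine, fingolimod); injectables are platform therapies.
DEFAULT_DMT_CATALOG: dict[str, DMTEntry] = {
    "alemtuzumab": DMTEntry(MAB, HIGH_EFFICACY),
    "natalizumab": DMTEntry(MAB, HIGH_EFFICACY),
    "ocrelizumab": DMTEntry(MAB, HIGH_EFFICACY),
    "ofatumumab": DMTEntry(MAB, HIGH_EFFICACY),
    "cladribine": DMTEntry(ORAL, HIGH_EFFICACY),
    "fingolimod": DMTEntry(ORAL, HIGH_EFFICACY),
    "dimethyl fumarate": DMTEntry(ORAL, PLATFORM),
    "teriflunomide": DMTEntry(ORAL, PLATFORM),
    "glatiramer acetate": DMTEntry(INJECTABLE, PLATFORM),
    "interferon beta": DMTEntry(INJECTABLE, PLATFORM),
    "peg-interferon beta": DMTEntry(INJECTABLE, PLATFORM),
}

#: Default ICD-9 codes flagging severe-disability conditions
#: (quadriplegia, paraplegia, unspecified hemiplegia).  Configurable: real
#: extracts should supply the locally validated list.
DEFAULT_SEVERE_DISABILITY_CODES = frozenset({"344.0", "344.1", "342.9"})

#: Outpatient service categories treated as MS-specific for case-finding.
#: Default: rehabilitation services, the category with the strongest
#: MS-specific signal in administrative outpatient flows.  Configurable.
DEFAULT_MS_OUTPATIENT_CATEGORIES = frozenset({"rehabilitation"})


@dataclass
class CodeLists:
    """Bundle of configurable code lists used in case-finding and features."""

    ms_icd9_code: str = MS_ICD9_CODE
    severe_disability_codes: frozenset[str] = field(
        default_factory=lambda: DEFAULT_SEVERE_DISABILITY_CODES
    )
    ms_outpatient_categories: frozenset[str] = field(
        default_factory=lambda: DEFAULT_MS_OUTPATIENT_CATEGORIES
    )


def validate_catalog(catalog: dict[str, DMTEntry]) -> None:
    for drug, entry in catalog.items():
        if entry.route_class not in (MAB, ORAL, INJECTABLE):
            raise ValueError(f"drug {drug!r}: unknown route_class {entry.route_class!r}")
        if entry.efficacy_tier not in (PLATFORM, HIGH_EFFICACY):
            raise ValueError(f"drug {drug!r}: unknown efficacy_tier {entry.efficacy_tier!r}")


def catalog_from_dict(raw: dict) -> dict[str, DMTEntry]:
    """Build a catalogue from a plain mapping, e.g. parsed YAML.

    Expected shape: ``{drug_name: {route_class: ..., efficacy_tier: ...}}``.
    """
    catalog = {
        str(drug): DMTEntry(str(v["route_class"]), str(v["efficacy_tier"]))
        for drug, v in raw.items()
    }
    validate_catalog(catalog)
    return catalog
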