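"""Default programme configuration: the four health signals and community
case definitions (CCDs) of the Somaliland CBS programme, and the SMS dialect.

Codes and thresholds:

====  ==============================================  =====================
code  health signal                                   community alert
                                                      threshold
====  ==============================================  =====================
2     Acute diarrhoeal disease (ADD)                  5 reports within
                                                      7 days in 20 km
4     Fever and rash                                  1 report
9     Fever, cough/difficulty breathing, tiredness    1 report
14    Cluster of unusual illnesses or death           1 report
====  ==============================================  =====================
"""

from __future__ import annotations

from .ingest import DialectConfig
from .ledger import CCDDefinition

__all__ = ["default_ccd_config", "default_dialect", "CLUSTER_CODE"]

CLUSTER_CODE = 2  # acute diarrhoeal disease


def default_ccd_config() -> tuple[CCDDefinition, ...]:
    return (
        CCDDefinition(
            code=2,
            name="Acute diarrhoeal disease (ADD)",
            case_definition=("Diarrhoea as 3 or more loose or liquid stools "
                             "over a period of 24 h"),
            target_events="Cholera",
            threshold_count=5,
            window_hours=168.0,
            radius_km=20.0,
        ),
        CCDDefinition(
            code=4,
            name="Fever and rash",
            case_definition=("Fever and rash, often accompanied by runny "
                             "nose, tiredness, headache, feeling unwell"),
            target_events="Measles, chicken pox",
            threshold_count=1,
        ),
        CCDDefinition(
            code=9,
            name="Fever, cough/difficulty breathing, and tiredness",
            case_definition=("Combination of 3 or more of: cough, difficulty "
                             "breathing, fever, runny nose, tiredness, "
                             "headache, feeling unwell, sore throat, "
                             "diarrhoea, loss of smell, loss of taste"),
            target_events="COVID-19",
            threshold_count=1,
        ),
        CCDDefinition(
            code=14,
            name="Cluster of unusual illnesses or death in people",
            case_definition=("Cluster of people (3+) suddenly sick or died "
                             "with the same signs of illness in the same "
                             "village area, in the past 2 weeks"),
            target_events="Unknown / emerging health threats",
            threshold_count=1,
        ),
    )


def default_dialect() -> DialectConfig:
    return DialectConfig(
        allowed_codes=tuple(c.code for c in default_ccd_config()),
        zero_token="0",
    )
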