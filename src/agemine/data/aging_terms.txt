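AGE-ASSOCIATED
AGE-CORRELATED
AGE-DEPENDENCE
AGE-DEPENDENT
AGED-OBESE
AGE-INDUCED
AGEING
AGEING-ASSOCIATED
AGEING-DEPENDENT
AGEING-INDUCED
AGEING-LIKE
AGEING-RELATED
AGEING-SUPPRESSOR
AGE-MATCHED
AGE-RELATED
AGE-SENSITIVE
AGE-SPECIFIC
AGING
AGING-ASSOCIATED
AGING-DEPENDENT
AGING-INDUCED
AGING-LIKE
AGING-RELATED
AGING-SUPPRESSOR
ANTI-AGEING
ANTI-AGING
HEALTH-RELATED
HEALTHSPAN
HEALTHSPANS
LIFE EXTENSION
LIFE-EXTENDING
LIFESPAN
LIFE-SPAN
LIFESPAN:
LIFESPANS
LIFE-SPANS
LONGEVITY
LONG-LIVED
LONG-LIVING
SENESCENCE
SENESCENCE-ACCELERATED
SENESCENCE-ASSOCIATED
SENESCENCE-LIKE
SENESCENCE-RELATED
SENESCENT
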