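# Rule pack for the four machine-readability barrier detectors.
# Patterns are Python regexes, matched case-insensitively against criterion
# text after length-preserving normalization of unicode comparators
# (see barrier_annotation._normalize).  The pack is data: detectors read it
# at run time and record its version in every output for provenance.
version: "ctgaudit-rules-1.0"

# Criteria about age or gender are structured registry fields already
# interpretable by machine; they are excluded from temporal and lab detection.
age_gender_exclusions:
  - '^(?:\d+[.)]\s*)?ages?\b'
  - '\byears?\s+of\s+age\b'
  - '\byears?\s+old\b'
  - '\bage\s*(?:<=|>=|<|>|=)'
  - '^(?:male|female)s?\s+(?:or\s+(?:male|female)s?\s+)?(?:patients?|subjects?)?\s*$'

temporal:
  # a quantity with a time unit ...
  quantity_unit: '(?:<=|>=|<|>)?\s*(?:\d+(?:\.\d+)?|one|two|three|four|five|six|seven|eight|nine|ten|twelve|twenty-four|forty-eight)[\s-]*(?:day|week|month|year|hour)s?\b'
  # ... anchored to a temporal relation
  anchors:
    - '\bsince\b'
    - '\bwithin\b'
    - '\bprior\b'
    - '\bbefore\b'
    - '\bafter\b'
    - '\bat\s+least\b'
    - '\bno\s+more\s+than\b'
    - '\bno\s+less\s+than\b'
    - '\bpast\b'
    - '\bprevious\b'
    - '\bfollowing\b'
    - '\bless\s+than\b'
    - '\bmore\s+than\b'
    - '\bover\s+the\s+last\b'
    - '[<>]'

lab_or_score:
  analytes:
    - '\banc\b'
    - '\babsolute\s+neutrophil\s+count\b'
    - '\bneutrophil\s+count\b'
    - '\bh(?:a)?emoglobin\b'
    - '\bh(?:a)?ematocrit\b'
    - '\bplatelet(?:\s+count)?s?\b'
    - '\bwbc\b'
    - '\bwhite\s+blood\s+cell\b'
    - '\bbilirubin\b'
    - '\bcreatinine(?:\s+clearance)?\b'
    - '\bast\b'
    - '\balt\b'
    - '\bsgot\b'
    - '\bsgpt\b'
    - '\btransaminases?\b'
    - '\balkaline\s+phosphatase\b'
    - '\balbumin\b'
    - '\binr\b'
    - '\bc-reactive\s+protein\b'
    - '\bcrp\b'
    - '\besr\b'
    - '\bhba1c\b'
    - '\bglucose\b'
    - '\bldh\b'
  scores:
    - '\becog(?:\s+performance\s+status)?\b'
    - '\bkarnofsky(?:\s+performance\s+status)?\b'
    - '\blansky(?:\s+play\s+scale)?\b'
    - '\bperformance\s+status\b'
    - '\bdas28\b'
    - '\bnyha\s+class\b'
    - '\bmmse\b'
    - '\bvisual\s+acuity\b'
    - '\bglasgow\s+coma\s+sc(?:ale|ore)\b'
  units:
    - '/\s*ul\b'
    - '/\s*mm3\b'
    - '\bmg\s*/\s*dl\b'
    - '\bg\s*/\s*dl\b'
    - '\biu\s*/\s*l\b'
    - '\bu\s*/\s*l\b'
    - '\bx\s*10\^?9\s*/\s*l\b'
    - '\bmmol\s*/\s*l\b'
    - '\bml\s*/\s*min\b'
    - '\bmg\s*/\s*l\b'
    - '\bmm\s*/\s*hr?\b'
    - '\bcells\s*/\s*mm3\b'
  # a number, range or comparator that gives the term a quantitative level
  numeric_context:
    - '(?:<=|>=|<|>|=)\s*\d[\d,]*(?:\.\d+)?'
    - '\b\d[\d,]*(?:\.\d+)?\s*(?:-|to)\s*\d[\d,]*(?:\.\d+)?\b'
    - '\b\d[\d,]*(?:\.\d+)?\b'

subpopulation:
  conditionals:
    - '^if\b'
    - '\bunless\b'
    - '\bonly\s+if\b'
    - '\bin\s+case\s+of\b'
    - '\bfor\s+(?:patients?|subjects?|participants?)\s+with\b'
    - '\bonly\s+appl(?:y|ies)\b'
  # a flat criterion naming a condition subgroup becomes a sub-population
  # marker when followed by deeper-indented child criteria
  subgroup_headers:
    - '\b(?:patients?|subjects?|participants?)\s+with\b'

patient_dependent:
  phrases:
    - '\bwilling(?:ness)?\s+to\b'
    - '\bable\s+to\b'
    - '\bability\s+to\b'
    - '\bmust\s+agree\s+to\b'
    - '\bagrees?\s+to\b'
    - '\bcapable\s+of\b'
    - '\bcomplian(?:ce|t)\s+with\b'
    - '\bconsents?\s+to\b'
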