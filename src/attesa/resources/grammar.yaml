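# Formal language of temporal waiting-time expressions.
#
# `subpatterns` are named regular-expression fragments; family patterns embed
# them with {{NAME}} placeholders, which the compiler substitutes recursively.
# A time unit, a number, a trigger word etc. are therefore written once and
# shared across every family that needs them.  New families can be added here
# without touching existing ones.
#
# Patterns carry no edge context (word boundaries, digit adjacency, "fa"
# suppression): those guards are applied uniformly by the scanner after
# matching, so that a substring either matches a family or not regardless of
# how it was found.  Alternations are ordered longest-first so greedy matching
# yields the longest form.

subpatterns:
  NUM: '\d{1,3}'
  NUM2: '\d{1,2}'
  YEAR4: '(?:19|20)\d{2}'
  YEAR: '(?:(?:19|20)\d{2}|\d{2})'
  UNIT: '(?:giorn[oi]|settiman[ae]|mes[ei]|ann[oi]|sett|set|gg|aa|g)'
  TRIGGER: '(?:tra|fra|entro|dopo|ogni|per|a|in)(?:\s+circa)?'
  FUP_KW: '(?:ricontrollo|controllo|follow\s*up|fup|rivalutazione|visita|ctr)'
  MONTH_NAME: '(?:gennaio|febbraio|marzo|aprile|maggio|giugno|luglio|agosto|settembre|ottobre|novembre|dicembre)'
  DATE_PREFIX: '(?:(?:entro|per|al|il|in)\s+(?:il\s+)?)?'
  WORD_FILL: '(?:[a-zà-ÿ]+\s+){0,2}?'

# post-processing thresholds live next to the grammar so a deployment tunes
# both in one place
normalizer:
  max_horizon_days: 730      # waiting times beyond two years are deleted as inconsistent
  range_policy: upper        # {upper, lower, midpoint}: day value taken from a range
  two_digit_year_window: 2000  # two-digit years resolve to 2000-2049; 50-99 -> 1900s (then rejected as past)

families:
  precise_date:
    priority: 60
    patterns:
      - '{{DATE_PREFIX}}(?P<day>{{NUM2}})(?P<dsep>[/.-])(?P<month>{{NUM2}})(?P=dsep)(?P<year>{{YEAR}})'
  range:
    priority: 50
    patterns:
      - '(?:tra|fra)\s+(?P<low>{{NUM}})\s+e\s+(?P<high>{{NUM}})\s*(?P<unit>{{UNIT}})'
      - '(?P<low>{{NUM}})\s*-\s*(?P<high>{{NUM}})\s*(?P<unit>{{UNIT}})'
  month_year:
    priority: 40
    patterns:
      - '(?:(?:entro|per|a|in)\s+)?(?P<monthname>{{MONTH_NAME}})\s+(?P<year>{{YEAR4}})'
  interval:
    priority: 30
    patterns:
      - '(?P<trigger>{{TRIGGER}})\s+(?P<value>{{NUM}})\s*(?P<unit>{{UNIT}})'
  bare_duration:
    priority: 20
    patterns:
      - '{{FUP_KW}}\s+{{WORD_FILL}}(?P<value>{{NUM}})\s*(?P<unit>{{UNIT}})'
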