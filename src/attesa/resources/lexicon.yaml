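# Temporal lexicon for the referral pre-processor and normalizer.
# All entries are lowercase; the pipeline lowercases before using them.

# plural / inflected temporal tokens -> lemma (dictionary lemmatizer backend)
unit_lemmas:
  giorni: giorno
  settimane: settimana
  mesi: mese
  anni: anno

# surface unit token -> canonical unit
unit_tokens:
  giorno: day
  giorni: day
  gg: day
  g: day
  settimana: week
  settimane: week
  sett: week
  set: week
  mese: month
  mesi: month
  anno: year
  anni: year
  aa: year

# tokens that start a waiting-time expression (or a therapy duration:
# "per 2 settimane"; the keyword-distance selection rule disambiguates)
trigger_words: [tra, fra, entro, dopo, ogni, per, a, in]

# keywords marking the follow-up request (used by bare durations and by
# the multiple-indication selection rule)
followup_keywords: [controllo, ricontrollo, follow up, followup, fup,
                    rivalutazione, visita, ctr]

# pregnancy context: trigger words and week-unit tokens; a number+week
# span near a trigger (clause-bounded window) is removed
pregnancy_triggers: [gravidanza, gravidica, gravida, gestazione, gestazionale,
                     gestante, amenorrea, s.g, sg]
pregnancy_week_units: [settimana, settimane, sett, set, sg, s.g, w]

# prepositions/articles glued to a gestational number, removed with it
pregnancy_attachers: [alla, della, nella, dalla, a, in, da, di, con, la, al]

# closed lexicon for partial typo correction (tokens >= 4 chars,
# edit distance <= 1, unique candidate only)
typo_lexicon: [controllo, ricontrollo, rivalutazione, visita, entro, dopo,
               tra, fra, ogni, circa, mese, mesi, settimana, settimane,
               giorno, giorni, anno, anni, follow, fup,
               gennaio, febbraio, marzo, aprile, maggio, giugno, luglio,
               agosto, settembre, ottobre, novembre, dicembre]

# Italian month names -> month number
months:
  gennaio: 1
  febbraio: 2
  marzo: 3
  aprile: 4
  maggio: 5
  giugno: 6
  luglio: 7
  agosto: 8
  settembre: 9
  ottobre: 10
  novembre: 11
  dicembre: 12
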