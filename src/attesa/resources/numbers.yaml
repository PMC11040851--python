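# Italian cardinal number words (1-60, tens to 90) and basic ordinals
# used by preprocess.words_to_digits; editable.
number_words:
  cinquanta: 50
  cinquantacinque: 55
  cinquantadue: 52
  cinquantanove: 59
  cinquantaquattro: 54
  cinquantasei: 56
  cinquantasette: 57
  cinquantatre: 53
  cinquantatré: 53
  cinquantotto: 58
  cinquantuno: 51
  cinque: 5
  diciannove: 19
  diciassette: 17
  diciotto: 18
  dieci: 10
  dodici: 12
  due: 2
  novanta: 90
  nove: 9
  ottanta: 80
  otto: 8
  quaranta: 40
  quarantacinque: 45
  quarantadue: 42
  quarantanove: 49
  quarantaquattro: 44
  quarantasei: 46
  quarantasette: 47
  quarantatre: 43
  quarantatré: 43
  quarantotto: 48
  quarantuno: 41
  quattordici: 14
  quattro: 4
  quindici: 15
  sedici: 16
  sei: 6
  sessanta: 60
  settanta: 70
  sette: 7
  tre: 3
  tredici: 13
  trenta: 30
  trentacinque: 35
  trentadue: 32
  trentanove: 39
  trentaquattro: 34
  trentasei: 36
  trentasette: 37
  trentatre: 33
  trentatré: 33
  trentotto: 38
  trentuno: 31
  un: 1
  una: 1
  undici: 11
  uno: 1
  venti: 20
  venticinque: 25
  ventidue: 22
  ventinove: 29
  ventiquattro: 24
  ventisei: 26
  ventisette: 27
  ventitre: 23
  ventitré: 23
  ventotto: 28
  ventuno: 21
ordinal_words:
  prima: 1
  primo: 1
  seconda: 2
  secondo: 2
  terza: 3
  terzo: 3
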