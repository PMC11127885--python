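composite_code,member1,member2,member3
avenstfa,avenste,avenfat,
bromhose,bromsec,bromhor,
galetesp,galetet,galespe,
eleounpa,eleouni,eleopal,
galiapsp,galiapa,galispu,
juncefco,junceff,junccon,
polypela,polyper,polylap,
ranuabr,ranuacr,ranubul,ranurep
ranurefl,ranurpt,ranufla,
stelpagr,stelplu,stelgra,
veropoag,veropol,veroagr,
vicihite,vicitet,vicihir,
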