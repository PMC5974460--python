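# lowercased abbreviations whose trailing period is not a sentence boundary
dr.
mr.
mrs.
ms.
prof.
rev.
st.
jr.
sr.
etc.
e.g.
i.e.
vs.
approx.
dept.
est.
fig.
no.
vol.
jan.
feb.
mar.
apr.
jun.
jul.
aug.
sep.
sept.
oct.
nov.
dec.
mon.
tue.
wed.
thu.
fri.
sat.
sun.
oz.
lb.
lbs.
mg.
ml.
a.m.
p.m.
u.s.
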