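category	group
i	pronoun
we	pronoun
you	pronoun
shehe	pronoun
they	pronoun
ipron	pronoun
assent	attitude
negate	attitude
swear	attitude
compare	attitude
interrog	attitude
affect	emotion
posemo	emotion
negemo	emotion
anx	emotion
anger	emotion
sad	emotion
insight	cognition
cause	cognition
discrep	cognition
tentat	cognition
certain	cognition
differ	cognition
percept	perception
see	perception
hear	perception
feel	perception
bio	bio
body	bio
health	bio
sexual	bio
ingest	bio
social	social
family	social
friend	social
female	social
male	social
drives	drives
affiliation	drives
achieve	drives
power	drives
reward	drives
risk	drives
focuspast	topic
focuspresent	topic
focusfuture	topic
space	topic
time	topic
work	topic
money	topic
relig	topic
death	topic
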