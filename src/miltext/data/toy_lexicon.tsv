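category	term
i	i
i	me
i	my
i	mine
i	myself
we	we
we	us
we	our
we	ours
we	ourselves
you	you
you	your
you	yours
you	yourself
shehe	she
shehe	he
shehe	her
shehe	him
shehe	his
shehe	hers
they	they
they	them
they	their
they	theirs
they	themselves
ipron	it
ipron	this
ipron	that
ipron	these
ipron	those
ipron	something
assent	yes
assent	agree
assent	ok
assent	okay
assent	absolutely
assent	sure
negate	no
negate	not
negate	never
negate	nothing
negate	cannot
swear	damn
swear	hell
swear	crap
swear	screw
swear	bloody
compare	better
compare	worse
compare	than
compare	most
compare	least
compare	unremarkable
compare	happiest
interrog	when
interrog	what
interrog	why
interrog	how
interrog	which
interrog	who
affect	feeling
affect	feelings
affect	mood
affect	emotion
affect	emotional
posemo	happy
posemo	joy
posemo	love
posemo	proud
posemo	beautiful
posemo	wonderful
posemo	grateful
negemo	bad
negemo	hurt
negemo	pain
negemo	awful
negemo	miserable
negemo	loss
anx	anxiety
anx	anxious
anx	worried
anx	nervous
anx	afraid
anx	fear
anger	angry
anger	rage
anger	hate
anger	furious
anger	annoyed
sad	sad
sad	cry
sad	grief
sad	lonely
sad	hopeless
sad	despair
insight	think
insight	know
insight	realize
insight	understand
insight	aware
insight	sense
cause	because
cause	reason
cause	cause
cause	effect
cause	hence
cause	therefore
discrep	should
discrep	would
discrep	could
discrep	wish
discrep	hope
discrep	expect
tentat	maybe
tentat	perhaps
tentat	guess
tentat	seems
tentat	unsure
tentat	confused
certain	always
certain	certainly
certain	definitely
certain	clearly
certain	truly
differ	but
differ	however
differ	although
differ	different
differ	else
differ	except
percept	look
percept	watch
percept	notice
percept	observe
percept	sense
see	see
see	saw
see	view
see	sight
see	scene
hear	hear
hear	listen
hear	sound
hear	voice
hear	noise
feel	feel
feel	felt
feel	touch
feel	warm
feel	cold
bio	life
bio	alive
bio	living
bio	breath
bio	blood
body	body
body	head
body	heart
body	hands
body	skin
body	bones
health	health
health	sick
health	tired
health	sleep
health	sleepless
health	insomnia
health	rest
sexual	kiss
sexual	hug
sexual	intimate
sexual	romance
sexual	desire
ingest	eat
ingest	food
ingest	drink
ingest	dinner
ingest	taste
ingest	hungry
social	talk
social	share
social	friends
social	people
social	together
social	company
family	family
family	mother
family	father
family	parents
family	home
family	entanglements
friend	friend
friend	buddy
friend	mate
friend	companion
friend	neighbor
female	woman
female	girl
female	mom
female	sister
female	aunt
male	man
male	boy
male	dad
male	brother
male	uncle
drives	motivation
drives	drive
drives	ambition
drives	aspiration
drives	pursuit
drives	quest
affiliation	belonging
affiliation	belong
affiliation	connect
affiliation	bond
affiliation	community
affiliation	member
achieve	achieve
achieve	goal
achieve	success
achieve	win
achieve	prize
achieve	accomplish
achieve	plans
power	power
power	control
power	lead
power	strong
power	authority
power	influence
reward	reward
reward	gain
reward	benefit
reward	earn
reward	bonus
reward	prize
risk	risk
risk	danger
risk	unsafe
risk	threat
risk	gamble
risk	lose
focuspast	was
focuspast	were
focuspast	yesterday
focuspast	ago
focuspast	remember
focuspast	memories
focuspresent	is
focuspresent	am
focuspresent	today
focuspresent	now
focuspresent	currently
focusfuture	will
focusfuture	tomorrow
focusfuture	future
focusfuture	soon
focusfuture	someday
space	place
space	room
space	city
space	space
space	inside
space	outside
time	time
time	hour
time	night
time	nights
time	morning
time	moment
time	during
work	work
work	job
work	office
work	career
work	task
work	project
money	money
money	cash
money	pay
money	salary
money	cost
money	spend
relig	faith
relig	pray
relig	spirit
relig	sacred
relig	worship
relig	soul
death	death
death	die
death	dead
death	funeral
death	mortal
death	grave
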