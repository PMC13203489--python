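# Default function-word lexicon: 10 closed-class categories.
# An approximation of the LIWC-tradition category lists; every analysis takes
# the lexicon as an input so these lists can be swapped without code change.
# Words must be lowercase and appear in at most one category.
first_person_sg:
  - i
  - me
  - my
  - mine
  - myself
  - i'm
  - i've
  - i'll
  - i'd
first_person_pl:
  - we
  - us
  - our
  - ours
  - ourselves
  - we're
  - we've
  - we'll
  - we'd
second_person:
  - you
  - your
  - yours
  - yourself
  - yourselves
  - you're
  - you've
  - you'll
  - you'd
third_person:
  - he
  - him
  - his
  - she
  - her
  - hers
  - they
  - them
  - their
  - theirs
  - himself
  - herself
  - themselves
  - it
  - its
  - itself
  - he's
  - she's
  - they're
  - they've
  - they'll
discourse_connectives:
  - however
  - therefore
  - moreover
  - furthermore
  - thus
  - hence
  - consequently
  - meanwhile
  - anyway
  - also
  - then
  - so
  - well
  - actually
  - basically
  - okay
  - ok
  - right
  - now
hedges:
  - maybe
  - perhaps
  - probably
  - possibly
  - apparently
  - somewhat
  - kinda
  - sorta
  - roughly
  - approximately
  - likely
  - presumably
  - arguably
  - fairly
  - quite
  - rather
  - almost
  - seems
  - seemed
articles:
  - a
  - an
  - the
prepositions:
  - in
  - "on"
  - at
  - by
  - with
  - from
  - to
  - of
  - for
  - about
  - into
  - over
  - under
  - between
  - through
  - during
  - before
  - after
  - against
  - among
  - within
  - without
  - across
  - behind
  - beyond
  - near
  - toward
  - towards
  - upon
  - "off"
  - above
  - below
  - around
conjunctions:
  - and
  - but
  - or
  - nor
  - yet
  - because
  - although
  - though
  - while
  - whereas
  - if
  - unless
  - until
  - since
  - when
  - whenever
  - where
  - wherever
  - as
negations:
  - not
  - "no"
  - never
  - none
  - nothing
  - nobody
  - nowhere
  - neither
  - don't
  - doesn't
  - didn't
  - won't
  - wouldn't
  - can't
  - cannot
  - couldn't
  - shouldn't
  - isn't
  - aren't
  - wasn't
  - weren't
  - ain't
  - hasn't
  - haven't
  - hadn't
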