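package,category
com.google.android.apps.messaging,messaging
com.samsung.android.messaging,messaging
com.whatsapp,messaging
org.telegram.messenger,messaging
org.thoughtcrime.securesms,messaging
com.facebook.orca,messaging
com.snapchat.android,messaging
com.discord,messaging
com.viber.voip,messaging
kik.android,messaging
com.groupme.android,messaging
com.facebook.katana,social_media
com.instagram.android,social_media
com.twitter.android,social_media
com.reddit.frontpage,social_media
com.zhiliaoapp.musically,social_media
com.tumblr,social_media
com.linkedin.android,social_media
com.pinterest,social_media
com.grindrapp.android,dating
com.tinder,dating
com.adam4adam.radar,dating
com.scruff.app,dating
com.bumble.app,dating
com.okcupid.okcupid,dating
com.match.android.matchmobile,dating
com.hornet.android,dating
com.jackd.android,dating
com.feeld.app,dating
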