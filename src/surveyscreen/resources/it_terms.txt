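# IT-jargon lexicon for the off-topic open-text rule (lowercased match)
software
hardware
interface
user interface
network
networking
bandwidth
server
database
website
web page
browser
application
app
login
password
username
download
upload
wifi
broadband
internet speed
processor
cpu
algorithm
operating system
windows 10
android
firmware
javascript
frontend
backend
cloud computing
data center
router
modem
encryption
debug
source code
html
gigabyte
megabyte
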